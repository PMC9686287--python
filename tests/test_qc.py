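"""Volume censoring, motion QC and nuisance regression."""

import numpy as np
import pytest

from fcdmap.qc import (BoldMatrix, NuisanceSet, apply_censoring,
                       censor_high_motion, flag_outlier_volumes,
                       framewise_displacement, nuisance_regress,
                       subject_passes_qc)


def _nuisance(T, rng=None, fd=None):
    rng = rng or np.random.default_rng(0)
    ns = NuisanceSet(
        motion6=rng.normal(0, 0.01, (T, 6)),
        tissue_signals=rng.standard_normal((T, 2)),
        physio=rng.standard_normal((T, 2)),
        framewise_displacement_mm=fd,
    )
    return ns


class TestOutlierVolumes:
    def test_planted_spike_volume_flagged(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((200, 100))
        spike_verts = np.arange(16)            # 8% of 200 vertices
        mad = np.median(np.abs(x - np.median(x, 1, keepdims=True)), axis=1)
        x[spike_verts, 50] += 10 * mad[spike_verts]
        flags = flag_outlier_volumes(BoldMatrix(values=x))
        assert flags[50]
        assert flags.sum() == 1

    def test_constant_data_flags_nothing(self):
        x = np.full((50, 40), 7.0)
        flags = flag_outlier_volumes(BoldMatrix(values=x))
        assert not flags.any()

    def test_three_planted_spikes_match_brute_force(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((300, 120))
        planted = [10, 60, 110]
        for t in planted:
            verts = rng.choice(300, 30, replace=False)
            x[verts, t] += 50.0
        bold = BoldMatrix(values=x)
        flags = flag_outlier_volumes(bold)
        # independent recount at the same multiplier
        from scipy.stats import norm
        k = norm.isf(0.001 / 120) * np.sqrt(np.pi / 2)
        med = np.median(x, axis=1, keepdims=True)
        mad = np.median(np.abs(x - med), axis=1, keepdims=True)
        expected = np.array([
            np.mean(np.abs(x[:, t] - med[:, 0]) > k * mad[:, 0]) > 0.05
            for t in range(120)
        ])
        np.testing.assert_array_equal(flags, expected)
        assert set(np.flatnonzero(flags)) == set(planted)

    def test_literal_multiplier_one_flags_every_volume(self):
        """Half of any continuous series exceeds its own MAD, so the literal
        one-MAD rule censors everything — why the default is the
        tail-calibrated multiplier."""
        rng = np.random.default_rng(2)
        x = rng.standard_normal((200, 50))
        flags = flag_outlier_volumes(BoldMatrix(values=x), mad_multiplier=1.0)
        assert flags.all()


class TestMotionCensoring:
    def test_low_motion_keeps_everything(self):
        ns = _nuisance(100, fd=np.full(100, 0.1))
        assert not censor_high_motion(ns).any()

    def test_single_exceedance(self):
        fd = np.full(100, 0.1)
        fd[42] = 0.31
        flags = censor_high_motion(_nuisance(100, fd=fd))
        assert flags.sum() == 1 and flags[42]

    def test_boundary_is_strict(self):
        fd = np.full(10, 0.30)
        assert not censor_high_motion(_nuisance(10, fd=fd)).any()

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            censor_high_motion(_nuisance(10), threshold_mm=-0.1)

    def test_fd_rotations_scaled_to_arc_length(self):
        motion = np.zeros((3, 6))
        motion[1, 3] = 0.002                   # 2 mrad rotation step
        fd = framewise_displacement(motion)
        assert np.isclose(fd[1], 0.002 * 50)
        assert fd[0] == 0.0


class TestSubjectQc:
    @pytest.mark.parametrize("censored,expected", [(0, True), (50, True),
                                                   (51, False)])
    def test_twenty_percent_rule_is_strict(self, censored, expected):
        mask = np.ones(250, dtype=bool)
        mask[:censored] = False
        assert subject_passes_qc(mask) is expected


class TestNuisanceRegression:
    def test_series_equal_to_regressor_vanishes(self):
        ns = _nuisance(120)
        bold = BoldMatrix(values=np.tile(ns.motion6[:, 2], (5, 1)))
        out = nuisance_regress(bold, ns)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-10)

    def test_orthogonal_data_unchanged_up_to_projection(self):
        rng = np.random.default_rng(3)
        T = 150
        ns = _nuisance(T, rng=rng)
        y = rng.standard_normal((4, T))
        # orthogonalize data against the full design by hand
        drift = np.linspace(-1, 1, T)
        cols, _ = ns.design_columns()
        X = np.column_stack([np.ones(T), drift, cols])
        H = X @ np.linalg.pinv(X)              # T x T projector onto design
        y_orth = y - y @ H
        out = nuisance_regress(BoldMatrix(values=y_orth), ns)
        np.testing.assert_allclose(out.values, y_orth, atol=1e-8)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        T = 180
        ns = _nuisance(T, rng=rng)
        y = rng.standard_normal((20, T))
        out = nuisance_regress(BoldMatrix(values=y), ns)
        drift = np.linspace(-1, 1, T)
        cols, _ = ns.design_columns()
        X = np.column_stack([np.ones(T), drift, cols])
        beta = np.linalg.solve(X.T @ X, X.T @ y.T)
        expected = y.T - X @ beta
        np.testing.assert_allclose(out.values, expected.T, atol=1e-8)
        # residuals orthogonal to every regressor
        assert np.abs(out.values @ X).max() < 1e-6

    def test_residual_variance_never_increases(self):
        rng = np.random.default_rng(5)
        ns = _nuisance(100, rng=rng)
        y = rng.standard_normal((10, 100)) + 0.5 * ns.motion6[:, 0]
        out = nuisance_regress(BoldMatrix(values=y), ns)
        assert (out.values.var(axis=1) <= y.var(axis=1) + 1e-12).all()

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(6)
        T = 100
        motion = rng.standard_normal((T, 6))
        motion[:, 5] = motion[:, 4]            # duplicated column
        ns = NuisanceSet(motion6=motion,
                         tissue_signals=rng.standard_normal((T, 1)),
                         physio=rng.standard_normal((T, 1)))
        with pytest.raises(ValueError, match="rank-deficient|collinear"):
            nuisance_regress(BoldMatrix(values=rng.standard_normal((3, T))),
                             ns)

    def test_censoring_operators_commute(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((50, 80))
        fd = np.full(80, 0.1)
        fd[5] = 1.0
        bold = BoldMatrix(values=x)
        ns = _nuisance(80, fd=fd)
        outl = flag_outlier_volumes(bold)
        mot = censor_high_motion(ns)
        ab = apply_censoring(bold, outl, mot).censor_mask
        ba = apply_censoring(bold, mot, outl).censor_mask
        np.testing.assert_array_equal(ab, ba)
        np.testing.assert_array_equal(ab, ~outl & ~mot)
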