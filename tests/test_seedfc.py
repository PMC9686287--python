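"""Seed-based resting-state FC: mean series, Fisher-z maps, masks."""

import numpy as np
import pytest

from fcdmap.inference.glm import GlmSpec
from fcdmap.qc import BoldMatrix
from fcdmap.seedfc import (SeedDefinition, group_positive_mask, seed_fc_map,
                           seed_mean_timeseries, seed_signal_intensity_check)
from fcdmap import synth


class TestSeedMean:
    def test_single_vertex_seed_returns_its_series(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((10, 50))
        s = seed_mean_timeseries(BoldMatrix(values=x),
                                 SeedDefinition(vertex_set=[4]))
        np.testing.assert_array_equal(s, x[4])

    def test_antiphase_pair_cancels(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(40)
        vals = np.vstack([x, -x, np.zeros(40)])
        s = seed_mean_timeseries(BoldMatrix(values=vals),
                                 SeedDefinition(vertex_set=[0, 1]))
        np.testing.assert_allclose(s, 0.0, atol=1e-12)

    def test_matches_column_mean(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((30, 60))
        seed = SeedDefinition(vertex_set=np.arange(10))
        s = seed_mean_timeseries(BoldMatrix(values=x), seed)
        np.testing.assert_allclose(s, x[:10].mean(axis=0))

    def test_fully_masked_seed_rejected(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((5, 20))
        mask = np.ones(5, dtype=bool)
        mask[[0, 1]] = False
        with pytest.raises(ValueError, match="mask"):
            seed_mean_timeseries(BoldMatrix(values=x),
                                 SeedDefinition(vertex_set=[0, 1]),
                                 vertex_mask=mask)


class TestSeedFcMap:
    def test_uncorrelated_vertex_maps_to_zero(self, icosphere2):
        rng = np.random.default_rng(4)
        n = icosphere2.n_vertices
        x = rng.standard_normal((n, 2000))
        fm = seed_fc_map(BoldMatrix(values=x),
                         SeedDefinition(vertex_set=[0]), icosphere2,
                         fwhm_mm=0.0)
        assert np.nanmean(np.abs(fm.z_values[1:])) < 0.05

    def test_fisher_z_of_0p6_is_ln2(self):
        assert np.isclose(np.arctanh(0.6), 0.6931, atol=1e-4)

    def test_seed_vertices_excluded(self, icosphere2):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((icosphere2.n_vertices, 100))
        seed = SeedDefinition(vertex_set=[3, 7])
        fm = seed_fc_map(BoldMatrix(values=x), seed, icosphere2, fwhm_mm=0.0)
        assert np.isnan(fm.z_values[[3, 7]]).all()

    def test_planted_coupling_recovers_designed_correlation(self, icosphere3):
        """Mean Fisher z over a coupled patch approximates atanh of the
        designed within-patch correlation r = alpha^2 / (alpha^2 + 1)."""
        truth = synth.default_truth(icosphere3, seed=6, n_background=0)
        cohort = synth.generate_cohort(4, 2, 2, seed=6)
        row = cohort.iloc[0]            # normoglycemic: baseline only
        zs = []
        for rep in range(6):
            bold, _ = synth.generate_bold(icosphere3, truth, row, seed=rep,
                                          n_motion_spikes=0)
            patch = np.flatnonzero(
                truth.patch_partition == truth.sr_patch)
            seed_def = SeedDefinition(vertex_set=patch[:1])
            fm = seed_fc_map(bold, seed_def, icosphere3, fwhm_mm=0.0)
            zs.append(np.nanmean(fm.z_values[patch[1:]]))
        assert abs(np.mean(zs) - np.arctanh(0.7)) < 0.05

    def test_fisher_z_is_odd_and_monotone(self):
        r = np.linspace(-0.9, 0.9, 19)
        z = np.arctanh(r)
        np.testing.assert_allclose(z, -np.arctanh(-r))
        assert (np.diff(z) > 0).all()


class TestPositiveMask:
    def test_strong_positive_fc_masks_everything(self):
        rng = np.random.default_rng(7)
        Z = 0.5 + 0.05 * rng.standard_normal((20, 100))
        mask = group_positive_mask({"a": Z, "b": Z + 0.01})
        assert mask.mean() > 0.95

    def test_null_fc_masks_nearly_nothing(self):
        rng = np.random.default_rng(8)
        Z = 0.03 * rng.standard_normal((20, 500))
        mask = group_positive_mask({"a": Z, "b": Z[::-1]})
        assert mask.mean() < 0.02

    def test_matches_per_vertex_t_oracle_and_union_monotone(self):
        from scipy import stats
        rng = np.random.default_rng(9)
        Za = rng.standard_normal((15, 200)) + np.linspace(-0.5, 0.8, 200)
        Zb = rng.standard_normal((15, 200))
        union = group_positive_mask({"a": Za, "b": Zb}, alpha=0.01)
        inter = group_positive_mask({"a": Za, "b": Zb}, alpha=0.01,
                                    combine="intersection")
        assert (inter <= union).all()
        t, p = stats.ttest_1samp(Za, 0.0, alternative="greater")
        mask_a = p < 0.01
        t, p = stats.ttest_1samp(Zb, 0.0, alternative="greater")
        np.testing.assert_array_equal(union, mask_a | (p < 0.01))

    def test_single_subject_group_rejected(self):
        with pytest.raises(ValueError):
            group_positive_mask({"a": np.zeros((1, 10))})


class TestSignalIntensityCheck:
    def _setup(self, offset):
        rng = np.random.default_rng(10)
        cohort = synth.generate_cohort(30, 15, 15, seed=10)
        raw = {}
        for _, row in cohort.iterrows():
            base = 1000.0 + (offset if row["group"] == "prediabetes" else 0)
            raw[row["id"]] = BoldMatrix(
                values=base + rng.standard_normal((20, 50)))
        spec = GlmSpec(terms=["group_code"], contrast="group_code",
                       covariates=["age"])
        return raw, cohort, spec

    def test_planted_offset_detected(self):
        raw, cohort, spec = self._setup(offset=5.0)
        table = seed_signal_intensity_check(
            raw, SeedDefinition(vertex_set=np.arange(10)), cohort, spec)
        assert table.loc[table["term"] == "group_code", "p"].iloc[0] < 0.01

    def test_no_offset_not_detected(self):
        raw, cohort, spec = self._setup(offset=0.0)
        table = seed_signal_intensity_check(
            raw, SeedDefinition(vertex_set=np.arange(10)), cohort, spec)
        assert table.loc[table["term"] == "group_code", "p"].iloc[0] > 0.01

    def test_constant_intensity_rejected(self):
        cohort = synth.generate_cohort(10, 5, 5, seed=11)
        raw = {i: BoldMatrix(values=np.full((5, 30), 7.0))
               for i in cohort["id"]}
        spec = GlmSpec(terms=["group_code"], contrast="group_code")
        with pytest.raises(ValueError, match="variance"):
            seed_signal_intensity_check(
                raw, SeedDefinition(vertex_set=[0]), cohort, spec)
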