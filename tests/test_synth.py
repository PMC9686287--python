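"""Synthetic cohort, surface and BOLD generators."""

import numpy as np
import pytest

from fcdmap import synth
from fcdmap.fcd import compute_fcd, compute_global_fcd, correlation_matrix
from fcdmap.qc import nuisance_regress


class TestCohort:
    def test_default_counts_match_study(self, cohort144):
        assert len(cohort144) == 144
        assert (cohort144["group"] == "prediabetes").sum() == 71
        assert (cohort144["sex_code"] == 0).sum() == 79
        sizes = cohort144.groupby(["group", "sex_code"]).size()
        assert sizes[("normoglycemia", 0)] == 39
        assert sizes[("normoglycemia", 1)] == 34
        assert sizes[("prediabetes", 0)] == 40
        assert sizes[("prediabetes", 1)] == 31

    def test_prediabetic_glucose_within_diagnostic_band(self, cohort144):
        g = cohort144.loc[cohort144["group"] == "prediabetes", "glucose"]
        assert ((g >= 5.6) & (g <= 6.9)).all()
        gn = cohort144.loc[cohort144["group"] == "normoglycemia", "glucose"]
        assert (gn < 5.6).all()

    def test_subgroup_glucose_means_match_targets_over_seeds(self):
        normo, pre = [], []
        for seed in range(25):
            c = synth.generate_cohort(seed=seed)
            normo.append(
                c.loc[c["group"] == "normoglycemia", "glucose"].mean())
            pre.append(c.loc[c["group"] == "prediabetes", "glucose"].mean())
        assert abs(np.mean(normo) - 5.0) < 0.1
        assert abs(np.mean(pre) - 6.1) < 0.1

    def test_group_label_consistent_with_classifier(self, cohort144):
        from fcdmap.cardio import classify_glycemia
        np.testing.assert_array_equal(
            cohort144["glycemia_class"],
            classify_glycemia(cohort144["glucose"].to_numpy()))
        assert (cohort144["group"] == cohort144["glycemia_class"]).all()

    def test_infeasible_counts_rejected(self):
        with pytest.raises(ValueError):
            synth.generate_cohort(10, 20, 5)

    def test_deterministic_given_seed(self):
        a = synth.generate_cohort(seed=5)
        b = synth.generate_cohort(seed=5)
        assert a.equals(b)


class TestSurface:
    @pytest.mark.parametrize("level,n", [(0, 12), (2, 162), (3, 642)])
    def test_icosphere_vertex_counts(self, level, n):
        assert synth.generate_surface(level).n_vertices == n

    def test_degrees_five_or_six(self, icosphere3):
        from fcdmap.surface import build_adjacency
        degs = {len(nb) for nb in build_adjacency(icosphere3)}
        assert degs == {5, 6}

    def test_diameter_scaling(self):
        mesh = synth.generate_surface(2, diameter_mm=100.0)
        radii = np.linalg.norm(mesh.vertex_coords, axis=1)
        np.testing.assert_allclose(radii, 50.0, rtol=1e-6)


class TestBold:
    def test_zero_coupling_has_no_connections(self, icosphere2):
        truth = synth.default_truth(icosphere2, n_patches=6, seed=0,
                                    within_patch_r=1e-6, lr_base_r=0.0,
                                    n_background=0, sr_homa_slope_r=0.0)
        cohort = synth.generate_cohort(4, 2, 2, seed=0)
        bold, _ = synth.generate_bold(icosphere2, truth, cohort.iloc[0],
                                      seed=0, n_motion_spikes=0)
        counts, _ = compute_global_fcd(bold)
        assert counts.mean() < 1.0

    def test_designed_within_patch_correlation_realized(self, icosphere3):
        truth = synth.default_truth(icosphere3, seed=1, n_background=0)
        cohort = synth.generate_cohort(4, 2, 2, seed=1)
        row = cohort.iloc[0]
        bold, nuis = synth.generate_bold(icosphere3, truth, row, seed=1,
                                         n_motion_spikes=0)
        clean = nuisance_regress(bold, nuis)
        R, _ = correlation_matrix(clean)
        vals = []
        for k in range(truth.n_patches):
            idx = np.flatnonzero(truth.patch_partition == k)
            if k == truth.sr_patch or len(idx) < 2:
                continue
            sub = R[np.ix_(idx, idx)]
            vals.append(sub[np.triu_indices(len(idx), 1)].mean())
        assert 0.65 < np.mean(vals) < 0.75

    def test_planted_group_sex_effect_recovered_end_to_end(self, icosphere3):
        """Across seeds, pre-diabetic females show higher long-range FCD at
        the planted hub than normoglycemic females; males do not."""
        diffs_f, diffs_m = [], []
        for seed in range(6):
            truth = synth.default_truth(icosphere3, seed=seed)
            cohort = synth.generate_cohort(8, 4, 4, seed=seed)
            hub = np.isin(truth.patch_partition,
                          [truth.hub_patch, truth.target_patch])
            lr = {}
            for k, (_, row) in enumerate(cohort.iterrows()):
                bold, _ = synth.generate_bold(icosphere3, truth, row,
                                              seed=seed * 100 + k,
                                              n_motion_spikes=0)
                res = compute_fcd(bold, icosphere3, smooth=False)
                lr[row["id"]] = res.long_range_fcd[hub].mean()
            c = cohort.set_index("id")
            f_pre = [lr[i] for i in c.index
                     if c.loc[i, "group_code"] == 1 and c.loc[i, "sex_code"] == 0]
            f_ng = [lr[i] for i in c.index
                    if c.loc[i, "group_code"] == 0 and c.loc[i, "sex_code"] == 0]
            m_pre = [lr[i] for i in c.index
                     if c.loc[i, "group_code"] == 1 and c.loc[i, "sex_code"] == 1]
            m_ng = [lr[i] for i in c.index
                    if c.loc[i, "group_code"] == 0 and c.loc[i, "sex_code"] == 1]
            diffs_f.append(np.mean(f_pre) - np.mean(f_ng))
            diffs_m.append(np.mean(m_pre) - np.mean(m_ng))
        assert np.mean(diffs_f) > 5.0
        assert abs(np.mean(diffs_m)) < np.mean(diffs_f) / 4

    def test_homa_attenuation_lowers_short_range_at_sr_patch(self,
                                                             icosphere3):
        truth = synth.default_truth(icosphere3, seed=2,
                                    sr_homa_slope_r=0.25)
        cohort = synth.generate_cohort(12, 12, 6, seed=2)
        pre = cohort[cohort["group_code"] == 1]
        lo = pre.nsmallest(3, "homa")
        hi = pre.nlargest(3, "homa")
        sr_patch = truth.patch_partition == truth.sr_patch
        hc, hs = float(pre["homa"].mean()), float(pre["homa"].std())

        def mean_sr(rows, tag):
            out = []
            for k, (_, row) in enumerate(rows.iterrows()):
                bold, _ = synth.generate_bold(
                    icosphere3, truth, row, seed=500 + k + tag,
                    homa_center=hc, homa_scale=hs, n_motion_spikes=0)
                res = compute_fcd(bold, icosphere3, smooth=False)
                out.append(res.short_range_fcd[sr_patch].mean())
            return np.mean(out)

        assert mean_sr(hi, 0) < mean_sr(lo, 50)

    def test_reproducible_given_seed(self, icosphere2):
        truth = synth.default_truth(icosphere2, n_patches=6, seed=3)
        cohort = synth.generate_cohort(4, 2, 2, seed=3)
        a, na = synth.generate_bold(icosphere2, truth, cohort.iloc[1], seed=9)
        b, nb = synth.generate_bold(icosphere2, truth, cohort.iloc[1], seed=9)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(na.motion6, nb.motion6)

    def test_invalid_designed_correlation_rejected(self, icosphere2):
        with pytest.raises(ValueError):
            synth.default_truth(icosphere2, n_patches=6, seed=0,
                                within_patch_r=1.0)


class TestNullDataset:
    def test_deterministic_and_effect_free(self, icosphere2):
        cohort = synth.generate_cohort(8, 4, 4, seed=4)
        a, truth_a = synth.make_null_dataset(icosphere2, cohort, seed=4,
                                             n_patches=6)
        b, _ = synth.make_null_dataset(icosphere2, cohort, seed=4,
                                       n_patches=6)
        i = cohort["id"].iloc[0]
        np.testing.assert_array_equal(a[i][0].values, b[i][0].values)
        assert truth_a.sr_homa_slope_r == 0.0
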