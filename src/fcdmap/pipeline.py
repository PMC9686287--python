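"""End-to-end orchestration: simulate -> QC -> FCD -> vertexwise statistics
-> seed FC -> cognition models.

Stages exchange file artifacts (cohort CSV, per-subject ``.npz`` arrays,
findings tables) under the configured output directory, so each stage is
independently rerunnable; a JSON manifest records the config hash, seeds and
per-stage counts.  Reruns with identical config and seed are bit-identical.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import qc as qcmod
from . import synth
from .config import COVARIATES, RunConfig, validate_config
from .fcd import compute_fcd
from .inference.bayes import jzs_bf10
from .inference.effects import bca_bootstrap_ci, cohens_d, effect_size_delta
from .inference.glm import GlmSpec, build_design, fit_vertexwise_glm, vif_check
from .inference.rft import (ClusterFinding, findings_table,
                            hierarchical_correction)
from .inference.cognition import cognition_moderation
from .seedfc import SeedDefinition, group_positive_mask, seed_fc_map
from .surface import SurfaceMesh, build_adjacency

__all__ = ["run_pipeline", "ContrastSpec", "default_contrasts",
           "group_level_analysis", "attach_cluster_statistics"]


@dataclass(frozen=True)
class ContrastSpec:
    """A named group-level model: measure, GLM terms and effect-size kind."""

    name: str
    measure: str                     # "short_range" | "long_range" | seed label
    glm: GlmSpec
    effect_kind: str                 # "d" | "d_within_female" | "delta"


def default_contrasts(measure: str) -> list[ContrastSpec]:
    """The study's three models for one connectivity measure: main effect of
    group (one-way ANCOVA), group x sex (two-way ANCOVA without sex among
    covariates), and group x HOMA moderation (without HOMA among
    covariates)."""
    cov = COVARIATES
    return [
        ContrastSpec(
            name=f"{measure}:group",
            measure=measure,
            glm=GlmSpec(terms=["group_code"], contrast="group_code",
                        covariates=[c for c in cov if c != "group_code"]),
            effect_kind="d",
        ),
        ContrastSpec(
            name=f"{measure}:group_x_sex",
            measure=measure,
            glm=GlmSpec(
                terms=["group_code", "sex_code", "group_code:sex_code"],
                contrast="group_code:sex_code",
                covariates=[c for c in cov if c != "sex_code"],
            ),
            effect_kind="d_within_female",
        ),
        ContrastSpec(
            name=f"{measure}:group_x_homa",
            measure=measure,
            glm=GlmSpec(
                terms=["group_code", "homa", "group_code:homa"],
                contrast="group_code:homa",
                covariates=[c for c in cov if c != "homa"],
            ),
            effect_kind="delta",
        ),
    ]


def group_level_analysis(
    maps_smoothed: np.ndarray,
    maps_unsmoothed: np.ndarray,
    cohort: pd.DataFrame,
    mesh: SurfaceMesh,
    contrast: ContrastSpec,
    config: RunConfig,
    analysis_mask: np.ndarray | None = None,
) -> list[ClusterFinding]:
    """Vertexwise GLM on smoothed and unsmoothed map stacks, hierarchical
    cluster correction, then cluster-level effect sizes, BCa CIs and BF10."""
    X, cols = build_design(cohort, contrast.glm)
    vif_check(X)
    res_sm = fit_vertexwise_glm(maps_smoothed, X, cols, contrast.name)
    res_un = fit_vertexwise_glm(maps_unsmoothed, X, cols, contrast.name)
    findings = hierarchical_correction(
        res_sm, res_un, mesh,
        p_vertex=config.p_vertex, p_cluster=config.p_cluster,
        q_fdr=config.q_fdr, method=config.correction_method,
        analysis_mask=analysis_mask,
        design=X, maps_smoothed=maps_smoothed, contrast_columns=cols,
        seed=config.seed,
    )
    for f in findings:
        attach_cluster_statistics(f, maps_smoothed, cohort, contrast, config)
    return findings


def _peak_values(maps: np.ndarray, finding: ClusterFinding) -> np.ndarray:
    return maps[:, finding.peak_vertex]


def attach_cluster_statistics(
    finding: ClusterFinding,
    maps_smoothed: np.ndarray,
    cohort: pd.DataFrame,
    contrast: ContrastSpec,
    config: RunConfig,
) -> None:
    """Fill effect size (+BCa CI) at the peak vertex and the JZS BF10 of the
    cluster-mean outcome (experimental vs covariate-only model)."""
    y_peak = _peak_values(maps_smoothed, finding)
    grp = cohort["group_code"].to_numpy()
    kind = contrast.effect_kind
    if kind in ("d", "d_within_female"):
        sel = (cohort["sex_code"].to_numpy() == 0
               if kind == "d_within_female"
               else np.ones(len(cohort), dtype=bool))
        data = pd.DataFrame({"y": y_peak[sel], "g": grp[sel]})

        def stat(d: pd.DataFrame) -> float:
            g0 = d.loc[d["g"] == 0, "y"].to_numpy()
            g1 = d.loc[d["g"] == 1, "y"].to_numpy()
            if len(g0) < 2 or len(g1) < 2 or (g0.var() + g1.var()) == 0:
                return 0.0
            return cohens_d(g0, g1)

        finding.effect_size = stat(data)
        finding.effect_size_kind = "d"
    else:                                           # delta for group x HOMA
        X, cols = build_design(cohort, contrast.glm)
        data = X.copy()
        data["_y"] = y_peak
        homa_pre = cohort.loc[cohort["group_code"] == 1, "homa"].to_numpy()
        j = list(X.columns).index(contrast.glm.contrast)

        def stat(d: pd.DataFrame) -> float:
            Xb = d[X.columns].to_numpy(float)
            yb = d["_y"].to_numpy(float)
            beta, *_ = np.linalg.lstsq(Xb, yb, rcond=None)
            resid = yb - Xb @ beta
            sd = resid.std(ddof=min(Xb.shape[1], len(yb) - 1))
            if sd == 0:
                return 0.0
            return effect_size_delta(beta[j], homa_pre, sd)

        finding.effect_size = stat(data)
        finding.effect_size_kind = "delta"
    lo, hi = bca_bootstrap_ci(stat, data, n_boot=config.n_boot,
                              seed=config.seed)
    finding.ci95_low, finding.ci95_high = lo, hi

    # Bayes factor on the cluster-mean measure: null = covariates (+ main
    # terms for an interaction contrast), full adds the predictor of interest
    y_mean = maps_smoothed[:, finding.vertex_set].mean(axis=1)
    X_full, _ = build_design(cohort, contrast.glm)
    X_null = X_full.drop(columns=[contrast.glm.contrast])
    bf10, label = jzs_bf10(y_mean, X_null, X_full,
                           r_scale=config.bf_r_scale)
    finding.bf10 = bf10
    finding.evidence_label = label


# ---------------------------------------------------------------------------
# pipeline stages

def _stack(maps: dict[str, dict[str, np.ndarray]], ids: list[str],
           measure: str) -> np.ndarray:
    return np.vstack([maps[i][measure] for i in ids])


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages on simulated data; returns the manifest."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {"config_hash": config.hash(), "seed": config.seed,
                      "stages": {}}
    config.to_json(os.path.join(config.out_dir, "config.json"))

    rng_seed = config.seed
    cohort = synth.generate_cohort(
        config.n_subjects, config.n_prediabetes, config.n_female,
        seed=rng_seed)
    mesh = synth.generate_surface(config.mesh_subdivisions)
    truth = synth.default_truth(mesh, n_patches=config.n_patches,
                                seed=rng_seed)
    data = synth.generate_dataset(mesh, truth, cohort,
                                  T=config.n_timepoints,
                                  tr=config.tr_seconds, seed=rng_seed)
    cohort.to_csv(os.path.join(config.out_dir, "cohort.csv"), index=False)
    manifest["stages"]["simulate"] = {
        "n_subjects": len(cohort), "n_vertices": mesh.n_vertices,
        "hub_patch": truth.hub_patch, "sr_patch": truth.sr_patch,
    }

    ids = cohort["id"].tolist()
    raw_bold = {i: data[i][0] for i in ids}

    # ---- QC ----
    if config.run_qc:
        n_censored = {}
        passed = {}
        cleaned = {}
        for i in ids:
            bold, nuis = data[i]
            outl = qcmod.flag_outlier_volumes(
                bold, vertex_fraction=config.outlier_fraction)
            mot = qcmod.censor_high_motion(
                nuis, threshold_mm=config.motion_threshold_mm)
            bold2 = qcmod.apply_censoring(bold, outl, mot)
            passed[i] = qcmod.subject_passes_qc(
                bold2.censor_mask, config.exclusion_fraction)
            n_censored[i] = int((~bold2.censor_mask).sum())
            cleaned[i] = qcmod.nuisance_regress(bold2, nuis)
        ids = [i for i in ids if passed[i]]
        cohort = cohort[cohort["id"].isin(ids)].reset_index(drop=True)
        pd.DataFrame({
            "id": list(n_censored), "n_censored": list(n_censored.values()),
            "passed": [passed[i] for i in n_censored],
        }).to_csv(os.path.join(config.out_dir, "qc_report.csv"), index=False)
        manifest["stages"]["qc"] = {
            "n_passed": len(ids),
            "total_censored_volumes": int(sum(n_censored.values())),
        }
    else:
        cleaned = {i: data[i][0] for i in ids}

    # ---- FCD ----
    adjacency = build_adjacency(mesh)
    fcd_sm: dict[str, dict[str, np.ndarray]] = {}
    fcd_un: dict[str, dict[str, np.ndarray]] = {}
    for i in ids:
        res = compute_fcd(cleaned[i], mesh, threshold_r=config.threshold_r,
                          fwhm_mm=config.fwhm_mm, adjacency=adjacency)
        if res.z_maps is None:
            raise RuntimeError(f"constant FCD map for subject {i}")
        fcd_sm[i] = {k: v.values for k, v in res.z_maps.items()}
        fcd_un[i] = dict(res.z_unsmoothed)
    np.savez_compressed(
        os.path.join(config.out_dir, "fcd_z_smoothed.npz"),
        **{f"{i}_{m}": fcd_sm[i][m] for i in ids for m in fcd_sm[i]})
    manifest["stages"]["fcd"] = {
        "threshold_r": config.threshold_r, "fwhm_mm": config.fwhm_mm,
        "n_subjects": len(ids),
    }

    # ---- vertexwise statistics on FCD ----
    all_findings: list[tuple[ContrastSpec, ClusterFinding]] = []
    if config.run_stats:
        for measure in ("short_range", "long_range"):
            sm = _stack(fcd_sm, ids, measure)
            un = _stack(fcd_un, ids, measure)
            for spec in default_contrasts(measure):
                found = group_level_analysis(
                    sm, un, cohort, mesh, spec, config)
                all_findings.extend((spec, f) for f in found)
        table = findings_table([f for _, f in all_findings])
        table.to_csv(os.path.join(config.out_dir, "fcd_findings.csv"),
                     index=False)
        manifest["stages"]["stats"] = {"n_clusters": len(all_findings)}

    # ---- seed FC ----
    seed_findings: list[tuple[ContrastSpec, ClusterFinding]] = []
    if config.run_seedfc and all_findings:
        for spec, finding in all_findings:
            seed = SeedDefinition(vertex_set=finding.vertex_set,
                                  label=f"seed_{spec.name}",
                                  source_contrast=spec.name)
            fc_sm = {}
            fc_un = {}
            for i in ids:
                fm = seed_fc_map(cleaned[i], seed, mesh,
                                 fwhm_mm=config.fwhm_mm)
                fc_sm[i] = {"fc": fm.z_values}
                raw_fm = seed_fc_map(cleaned[i], seed, mesh, fwhm_mm=0.0)
                fc_un[i] = {"fc": raw_fm.z_values}
            sm = _stack(fc_sm, ids, "fc")
            un = _stack(fc_un, ids, "fc")
            by_group = {
                g: sm[(cohort["group"] == g).to_numpy()]
                for g in ("normoglycemia", "prediabetes")
            }
            pos_mask = group_positive_mask(by_group, alpha=config.p_vertex)
            pos_mask[seed.vertex_set] = False
            for fc_spec in default_contrasts(seed.label):
                found = group_level_analysis(
                    sm, un, cohort, mesh, fc_spec, config,
                    analysis_mask=pos_mask & np.isfinite(sm).all(axis=0),
                )
                seed_findings.extend((fc_spec, f) for f in found)
        findings_table([f for _, f in seed_findings]).to_csv(
            os.path.join(config.out_dir, "seedfc_findings.csv"), index=False)
        manifest["stages"]["seedfc"] = {"n_clusters": len(seed_findings)}

    # ---- cognition ----
    if config.run_cognition and all_findings:
        rows = []
        scores = {"mmse": False, "tol": True, "tmt_a": True, "tmt_b": True,
                  "phonetic_fluency": False, "semantic_fluency": False,
                  "spatial_span": False}
        moderator_sets = {
            "group": ["group_code"],
            "group_sex": ["group_code", "sex_code"],
            "group_homa": ["group_code", "homa"],
        }
        for spec, finding in all_findings:
            sm = _stack(fcd_sm, ids, spec.measure)
            measure = sm[:, finding.vertex_set].mean(axis=1)
            for score, worse in scores.items():
                for mod_name, mods in moderator_sets.items():
                    res = cognition_moderation(
                        measure, cohort[score].to_numpy(), cohort,
                        moderators=mods,
                        covariates=[c for c in COVARIATES
                                    if c not in mods],
                        higher_is_worse=worse,
                        n_boot=config.n_boot, seed=config.seed,
                    )
                    rows.append({
                        "cluster": spec.name, "score": score,
                        "moderators": mod_name, "f": res.f, "p": res.p,
                        "bf10": res.bf10, "effect_size": res.effect_size,
                        "ci_low": res.ci95[0], "ci_high": res.ci95[1],
                        "valid": res.valid,
                    })
        pd.DataFrame(rows).to_csv(
            os.path.join(config.out_dir, "cognition_models.csv"), index=False)
        manifest["stages"]["cognition"] = {"n_models": len(rows)}

    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
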