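"""Synthetic cohorts, cortical meshes and surface BOLD with planted effects.

The generator emulates the study conditions: a 144-subject cohort (73
normoglycemia / 71 pre-diabetes, 79 females) with subgroup biomarker
distributions matching the published summary table; an icosphere mesh scaled
to a 100 mm diameter standing in for the registered cortical surface; and
250-volume, TR = 2 s vertex x time BOLD series with patch-structured local
correlations, hub-mediated long-range correlations, nuisance contamination
(motion, drift, tissue and physiological signals) and two plantable effects:

* a group x sex long-range coupling — pre-diabetic females acquire a
  suprathreshold correlation between a "precuneus-like" hub patch and a
  distant target patch, raising their long-range FCD there;
* a group x HOMA short-range attenuation — within-patch coupling at an
  "mOFC-like" patch weakens with insulin resistance across pre-diabetic
  subjects, lowering short-range FCD.

Within-patch coupling alpha is set from the designed correlation r through
r = alpha^2 / (alpha^2 + sigma^2), so empirical correlations have a closed
form to test against.  Everything is deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from . import cardio
from .qc import BoldMatrix, NuisanceSet
from .surface import SurfaceMesh

__all__ = [
    "TABLE1_PARAMS",
    "SyntheticTruth",
    "generate_cohort",
    "generate_surface",
    "default_truth",
    "generate_bold",
    "generate_dataset",
    "make_null_dataset",
]

# Subgroup mean/SD parameters (normo-F, normo-M, pre-F, pre-M) mirroring the
# published cohort table.  Height and SRPA are synthetic-only defaults (no
# printed values exist); insulin is in conventional units (mU/l).
TABLE1_PARAMS: dict[str, tuple] = {
    #                 NG-F          NG-M          PD-F          PD-M
    "age":          ((66.9, 5.7), (68.3, 4.9), (66.9, 4.4), (68.4, 4.0)),
    "education":    ((10.1, 5.3), (9.2, 5.2), (10.2, 5.1), (10.8, 4.6)),
    "bmi":          ((26.2, 3.5), (26.1, 3.0), (27.9, 3.2), (28.8, 4.3)),
    "waist":        ((86.2, 9.6), (89.5, 8.6), (92.5, 9.7), (97.1, 10.9)),
    "adiponectin":  ((6.5, 2.7), (7.7, 2.2), (6.2, 1.7), (7.6, 1.8)),
    "leptin":       ((22.7, 14.4), (13.2, 15.7), (24.4, 16.4), (10.6, 8.9)),
    "ldl":          ((3.4, 0.8), (3.1, 0.9), (3.4, 0.8), (3.1, 0.7)),
    "hdl":          ((1.5, 0.3), (1.5, 0.4), (1.6, 0.5), (1.5, 0.6)),
    "triglycerides": ((1.0, 0.4), (1.3, 0.6), (1.6, 0.9), (1.3, 0.7)),
    "glucose":      ((5.0, 0.3), (5.0, 0.4), (6.1, 0.4), (6.1, 0.4)),
    "insulin":      ((6.6, 2.7), (9.2, 7.6), (11.4, 5.4), (10.4, 4.3)),
    "heart_rate":   ((64.5, 9.3), (64.1, 11.4), (68.7, 10.4), (66.4, 10.9)),
    "sbp":          ((129.2, 21.3), (130.3, 24.2), (133.4, 19.3),
                     (139.3, 17.3)),
    "height":       ((162.0, 6.0), (175.0, 7.0), (162.0, 6.0), (175.0, 7.0)),
}

COGNITION_PARAMS: dict[str, tuple] = {
    "mmse":             ((28.4, 1.3), (28.2, 1.4), (28.3, 1.3), (28.4, 1.3)),
    "phonetic_fluency": ((13.6, 5.1), (15.5, 4.7), (15.3, 4.5), (15.9, 5.0)),
    "semantic_fluency": ((20.1, 6.6), (22.2, 5.2), (23.3, 6.1), (21.0, 6.1)),
    "tmt_a":            ((45.8, 21.9), (39.9, 14.2), (41.3, 14.3),
                         (34.4, 10.9)),
    "tmt_b":            ((122.2, 63.7), (103.5, 48.1), (132.0, 82.4),
                         (89.3, 41.1)),
    "tol":              ((379.8, 140.0), (348.8, 136.5), (409.6, 165.7),
                         (371.1, 134.4)),
    "spatial_span":     ((13.1, 3.1), (14.6, 3.0), (13.5, 2.9), (13.9, 2.7)),
}

# published subgroup sizes: (normo-F, normo-M, pre-F, pre-M)
_DEFAULT_SUBGROUPS = (39, 34, 40, 31)

GLUCOSE_BOUNDS = {
    "normoglycemia": (3.8, 5.6 - 1e-9),
    "prediabetes": (5.6, 6.9),
}


def _truncated_normal(rng, mean, sd, low, high, size):
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size * 2)
        draw = draw[(draw >= low) & (draw <= high)]
        take = min(len(draw), size - filled)
        out[filled: filled + take] = draw[:take]
        filled += take
    return out


def generate_cohort(
    n: int = 144,
    n_prediabetes: int = 71,
    n_female: int = 79,
    seed: int | None = 0,
    cognition_slopes: dict[str, tuple[str, float, bool]] | None = None,
) -> pd.DataFrame:
    """Sample a cohort table with subgroup distributions of the study.

    Subgroup sizes follow the published table when the defaults are used and
    proportional rounding otherwise.  Derived columns (HOMA, CRF, MS, A/L,
    group) are appended through the cardiometabolic estimators.

    ``cognition_slopes`` optionally plants linear dependence of a cognition
    score on a cohort column: ``{score: (column, slope_per_sd, pre_only)}``.
    """
    if not (0 <= n_prediabetes <= n and 0 <= n_female <= n):
        raise ValueError("infeasible cohort counts")
    rng = np.random.default_rng(seed)
    if (n, n_prediabetes, n_female) == (144, 71, 79):
        ng_f, ng_m, pd_f, pd_m = _DEFAULT_SUBGROUPS
    else:
        pd_f = int(round(n_prediabetes * n_female / n))
        pd_f = min(pd_f, n_female, n_prediabetes)
        pd_m = n_prediabetes - pd_f
        ng_f = n_female - pd_f
        ng_m = n - n_prediabetes - ng_f
        if min(ng_f, ng_m, pd_f, pd_m) < 0:
            raise ValueError("infeasible cohort counts")
    sizes = (ng_f, ng_m, pd_f, pd_m)
    groups = (["normoglycemia"] * (ng_f + ng_m)
              + ["prediabetes"] * (pd_f + pd_m))
    sexes = [0] * ng_f + [1] * ng_m + [0] * pd_f + [1] * pd_m

    rows: dict[str, np.ndarray] = {}
    for col, params in {**TABLE1_PARAMS, **COGNITION_PARAMS}.items():
        chunks = []
        for k, size in enumerate(sizes):
            mean, sd = params[k]
            if col == "glucose":
                lo, hi = GLUCOSE_BOUNDS[
                    "normoglycemia" if k < 2 else "prediabetes"]
                chunks.append(_truncated_normal(rng, mean, sd, lo, hi, size))
            elif col in ("insulin", "leptin", "adiponectin",
                         "triglycerides", "hdl", "ldl"):
                chunks.append(
                    _truncated_normal(rng, mean, sd, 0.2, np.inf, size))
            else:
                chunks.append(rng.normal(mean, sd, size))
        rows[col] = np.concatenate(chunks)
    rows["srpa"] = rng.integers(1, 6, n).astype(float)
    rows["mmse"] = np.clip(np.round(rows["mmse"]), 24, 30)
    rows["spatial_span"] = np.clip(np.round(rows["spatial_span"]), 4, 20)

    df = pd.DataFrame(rows)
    df.insert(0, "id", [f"sub-{i:03d}" for i in range(n)])
    df.insert(1, "group", groups)
    df.insert(2, "sex_code", sexes)
    df["group_code"] = (df["group"] == "prediabetes").astype(int)
    df = cardio.add_derived_columns(df)
    df["glycemia_class"] = cardio.classify_glycemia(df["glucose"].to_numpy())
    if cognition_slopes:
        for score, (col, slope, pre_only) in cognition_slopes.items():
            x = df[col].to_numpy(dtype=float)
            zx = (x - x.mean()) / x.std()
            gate = df["group_code"].to_numpy() if pre_only else 1.0
            df[score] = (df[score]
                         + slope * df[score].std() * zx * gate)
    return df


def generate_surface(subdivision_level: int = 3,
                     diameter_mm: float = 100.0) -> SurfaceMesh:
    """Icosphere mesh (10 * 4^level + 2 vertices) scaled to the given
    diameter, standing in for a registered hemisphere pair."""
    if subdivision_level < 0:
        raise ValueError("subdivision_level must be >= 0")
    ico = trimesh.creation.icosphere(
        subdivisions=subdivision_level, radius=diameter_mm / 2.0)
    return SurfaceMesh(
        vertex_coords=np.asarray(ico.vertices, float),
        triangles=np.asarray(ico.faces, np.int64),
        hemisphere_label="both",
    )


@dataclass
class SyntheticTruth:
    """Ground truth of the generative model for one simulated study.

    ``patch_partition`` assigns every vertex to a connected patch; the two
    named hub patches carry the plantable effects.  Designed correlations
    are Pearson r in (0, 1) realized through signal amplitudes via
    r = alpha^2 / (alpha^2 + sigma^2).
    """

    patch_partition: np.ndarray
    hub_patch: int                      # "precuneus-like" long-range hub
    target_patch: int                   # distant coupling target
    sr_patch: int                       # "mOFC-like" short-range hub
    within_patch_r: float = 0.7
    # baseline hub-target coupling is present but clearly sub-threshold, so
    # the planted effect toggles detectability rather than amplitude
    lr_base_r: float = 0.50
    lr_effect_r: float = 0.7            # hub-target r for pre-diabetic females
    sr_homa_slope_r: float = 0.12       # drop in within-patch r per HOMA SD
    # connector patches share one weak global signal with pairwise designed
    # r just below threshold, giving every subject a fluctuating long-range
    # count background (real cortex has distributed long-range hubs; an
    # all-zero lrFCD map would be constant and unusable)
    background_patches: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64))
    background_r: float = 0.58
    noise_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.patch_partition = np.asarray(self.patch_partition, dtype=np.int64)
        for name in ("within_patch_r", "lr_effect_r"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1); got {v}")
        if not (0 <= self.lr_base_r < 1):
            raise ValueError("lr_base_r must lie in [0, 1)")
        for p in (self.hub_patch, self.target_patch, self.sr_patch):
            if p not in self.patch_partition:
                raise ValueError(f"patch id {p} not present in partition")
        self.background_patches = np.asarray(self.background_patches,
                                             dtype=np.int64)
        if not (0 < self.background_r < 1):
            raise ValueError("background_r must lie in (0, 1)")

    @property
    def n_patches(self) -> int:
        return int(self.patch_partition.max()) + 1

    @property
    def effect_spec(self) -> dict[str, dict]:
        return {
            "long_range_hub": {
                "patch": self.hub_patch, "target": self.target_patch,
                "moderator": "group x sex (pre-diabetic females)",
                "base_r": self.lr_base_r, "effect_r": self.lr_effect_r,
            },
            "short_range_hub": {
                "patch": self.sr_patch,
                "moderator": "group x HOMA (pre-diabetic, per SD)",
                "slope_r": self.sr_homa_slope_r,
            },
        }


def _kmeans_patches(mesh: SurfaceMesh, n_patches: int, seed: int) -> np.ndarray:
    """Voronoi-style connected patches from seeded Lloyd iterations on
    vertex coordinates (patches of a convex surface Voronoi are connected)."""
    rng = np.random.default_rng(seed)
    coords = mesh.vertex_coords
    centers = coords[rng.choice(len(coords), n_patches, replace=False)]
    for _ in range(25):
        d = ((coords[:, None, :] - centers[None]) ** 2).sum(axis=2)
        labels = d.argmin(axis=1)
        for k in range(n_patches):
            sel = labels == k
            if sel.any():
                centers[k] = coords[sel].mean(axis=0)
    return labels


def default_truth(mesh: SurfaceMesh, n_patches: int = 24,
                  seed: int = 0, n_background: int = 8,
                  **kwargs) -> SyntheticTruth:
    """Partition the mesh, pick hub/target/sr patches far apart, and assign
    background connector patches among the remainder."""
    labels = _kmeans_patches(mesh, n_patches, seed)
    centroids = np.array([
        mesh.vertex_coords[labels == k].mean(axis=0) for k in range(n_patches)
    ])
    hub = 0
    target = int(((centroids - centroids[hub]) ** 2).sum(axis=1).argmax())
    # sr patch: far from both hub and target
    d = (((centroids - centroids[hub]) ** 2).sum(axis=1)
         * ((centroids - centroids[target]) ** 2).sum(axis=1))
    sr = int(d.argmax())
    remaining = [k for k in range(n_patches) if k not in (hub, target, sr)]
    n_bg = max(0, min(n_background, len(remaining)))
    rng = np.random.default_rng(seed)
    background = rng.choice(remaining, size=n_bg, replace=False)
    return SyntheticTruth(patch_partition=labels, hub_patch=hub,
                          target_patch=target, sr_patch=sr,
                          background_patches=np.sort(background),
                          rng_seed=seed, **kwargs)


def _alpha_for_r(r: float, sigma: float) -> float:
    """Amplitude realizing within-patch correlation r at noise SD sigma."""
    return sigma * np.sqrt(r / (1.0 - r))


def _subject_couplings(truth: SyntheticTruth, subject: pd.Series,
                       homa_center: float, homa_scale: float
                       ) -> tuple[float, np.ndarray]:
    """(hub-target coupling r, per-patch within-r) for one subject."""
    pre = str(subject["group"]) == "prediabetes"
    female = int(subject["sex_code"]) == 0
    lr_r = truth.lr_effect_r if (pre and female) else truth.lr_base_r
    within = np.full(truth.n_patches, truth.within_patch_r)
    if pre and truth.sr_homa_slope_r != 0:
        homa_z = (float(subject["homa"]) - homa_center) / homa_scale
        within[truth.sr_patch] = np.clip(
            truth.within_patch_r - truth.sr_homa_slope_r * homa_z,
            0.05, 0.95,
        )
    return lr_r, within


def generate_bold(
    mesh: SurfaceMesh,
    truth: SyntheticTruth,
    subject: pd.Series,
    T: int = 250,
    tr: float = 2.0,
    seed: int | None = 0,
    homa_center: float | None = None,
    homa_scale: float | None = None,
    baseline: float = 1000.0,
    group_intensity_offset: float = 0.0,
    n_motion_spikes: int = 2,
) -> tuple[BoldMatrix, NuisanceSet]:
    """One subject's vertex x time BOLD plus its nuisance table.

    Vertex series: baseline + alpha_patch * s_patch + beta * c_hub (hub and
    target patches only) + nuisance leakage + sigma * noise.  Amplitudes are
    set from the designed correlations; hub-target coupling beta solves
    beta^2 / (alpha^2 + beta^2 + sigma^2) = r_coupling.
    """
    rng = np.random.default_rng(seed)
    n_vert = mesh.n_vertices
    sigma = truth.noise_sd
    if homa_center is None:
        homa_center = float(subject.get("homa", 2.0))
    if homa_scale is None:
        homa_scale = 1.0
    lr_r, within = _subject_couplings(truth, subject, homa_center, homa_scale)

    patch_sig = rng.standard_normal((truth.n_patches, T))
    hub_sig = rng.standard_normal(T)
    noise = rng.standard_normal((n_vert, T)) * sigma

    alpha = _alpha_for_r(within, sigma)[truth.patch_partition]
    values = alpha[:, None] * patch_sig[truth.patch_partition] + noise
    if lr_r > 0:
        in_lr = np.isin(truth.patch_partition,
                        [truth.hub_patch, truth.target_patch])
        a2 = alpha[in_lr] ** 2
        beta = np.sqrt(lr_r * (a2 + sigma ** 2) / (1.0 - lr_r))
        values[in_lr] += beta[:, None] * hub_sig
    if len(truth.background_patches):
        bg_sig = rng.standard_normal(T)
        in_bg = np.isin(truth.patch_partition, truth.background_patches)
        a2 = alpha[in_bg] ** 2
        lam = np.sqrt(truth.background_r * (a2 + sigma ** 2)
                      / (1.0 - truth.background_r))
        values[in_bg] += lam[:, None] * bg_sig

    # nuisance structure: slow drift, motion leakage, tissue + physio
    t = np.arange(T)
    drift = np.linspace(-1, 1, T)
    step_sd = np.array([0.02] * 3 + [2e-4] * 3)   # mm translations, rad rots
    motion = np.cumsum(rng.normal(0, 1, (T, 6)) * step_sd, axis=0)
    spike_idx = (rng.choice(np.arange(5, T), size=n_motion_spikes,
                            replace=False) if n_motion_spikes
                 else np.empty(0, dtype=int))
    motion[spike_idx, :3] += rng.normal(0, 0.4, (len(spike_idx), 3))
    tissue = np.column_stack([
        rng.standard_normal(T), rng.standard_normal(T)])      # WM, CSF
    physio = np.column_stack([
        np.sin(2 * np.pi * 1.0 * t * tr / 4.0) + 0.3 * rng.standard_normal(T),
        np.sin(2 * np.pi * t * tr / 12.0) + 0.3 * rng.standard_normal(T),
    ])
    leak = (0.2 * drift + 0.15 * tissue[:, 0] + 0.1 * physio[:, 0])
    values = values + leak[None, :]
    values += baseline
    if group_intensity_offset and str(subject["group"]) == "prediabetes":
        values += group_intensity_offset

    nuis = NuisanceSet(motion6=motion, tissue_signals=tissue, physio=physio)
    bold = BoldMatrix(values=values, tr_seconds=tr,
                      subject_id=str(subject.get("id", "")))
    return bold, nuis


def generate_dataset(
    mesh: SurfaceMesh,
    truth: SyntheticTruth,
    cohort: pd.DataFrame,
    T: int = 250,
    tr: float = 2.0,
    seed: int = 0,
    **kwargs,
) -> dict[str, tuple[BoldMatrix, NuisanceSet]]:
    """Deterministic per-subject BOLD + nuisance for a whole cohort.

    HOMA moderation is standardized against the pre-diabetic subgroup so the
    planted slope is expressed per within-group SD."""
    pre = cohort[cohort["group"] == "prediabetes"]
    homa_center = float(pre["homa"].mean()) if len(pre) else 2.0
    homa_scale = float(pre["homa"].std()) if len(pre) > 1 else 1.0
    seeds = np.random.SeedSequence(seed).spawn(len(cohort))
    out = {}
    for (_, row), ss in zip(cohort.iterrows(), seeds):
        bold, nuis = generate_bold(
            mesh, truth, row, T=T, tr=tr,
            seed=np.random.default_rng(ss),
            homa_center=homa_center, homa_scale=homa_scale, **kwargs,
        )
        out[str(row["id"])] = (bold, nuis)
    return out


def make_null_dataset(
    mesh: SurfaceMesh,
    cohort: pd.DataFrame,
    seed: int = 0,
    n_patches: int = 24,
    T: int = 250,
    **kwargs,
) -> tuple[dict[str, tuple[BoldMatrix, NuisanceSet]], SyntheticTruth]:
    """Same generative process with every effect amplitude set to zero
    (baseline patch structure retained) — for FWE calibration."""
    null_truth = default_truth(mesh, n_patches=n_patches, seed=seed,
                               sr_homa_slope_r=0.0)
    seeds = np.random.SeedSequence(seed).spawn(len(cohort))
    data = {}
    for (_, row), ss in zip(cohort.iterrows(), seeds):
        neutral = row.copy()
        neutral["group"] = "normoglycemia"     # disables both planted effects
        bold, nuis = generate_bold(
            mesh, null_truth, neutral, T=T, seed=np.random.default_rng(ss),
            **kwargs,
        )
        bold.subject_id = str(row["id"])
        data[str(row["id"])] = (bold, nuis)
    return data, null_truth
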