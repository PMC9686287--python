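"""Seed-to-whole-cortex resting-state functional connectivity.

Clusters with FCD significantly associated with pre-diabetes serve as seeds:
the mean BOLD series over the seed's vertices is correlated with every other
cortical vertex, correlations are Fisher-z transformed (atanh) and smoothed.
A one-sided one-sample t-test per group identifies vertices with reliably
positive FC; the union of the two group masks restricts subsequent
statistics.  Because orbitofrontal/inferotemporal seeds may sit in signal
dropout, a seed-region mean-intensity model (same design as the main
analysis) is provided as a sanity check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .inference.glm import GlmSpec, build_design, fit_vertexwise_glm
from .qc import BoldMatrix
from .surface import CorticalMap, SurfaceMesh, geodesic_smooth

__all__ = [
    "SeedDefinition",
    "FcMap",
    "seed_mean_timeseries",
    "seed_fc_map",
    "group_positive_mask",
    "seed_signal_intensity_check",
]

_R_CAP = 1.0 - 1e-7


@dataclass(frozen=True)
class SeedDefinition:
    """A set of mesh vertices acting as an FC seed."""

    vertex_set: np.ndarray
    label: str = ""
    source_contrast: str = ""

    def __post_init__(self) -> None:
        vs = np.unique(np.asarray(self.vertex_set, dtype=np.int64))
        if vs.size == 0:
            raise ValueError("seed must be non-empty")
        if vs.min() < 0:
            raise ValueError("negative vertex index in seed")
        object.__setattr__(self, "vertex_set", vs)


@dataclass
class FcMap:
    """Fisher-z FC of one subject with one seed; seed vertices are NaN."""

    z_values: np.ndarray
    seed: SeedDefinition
    subject_id: str = ""
    smoothing_fwhm_mm: float = 0.0


def seed_mean_timeseries(bold: BoldMatrix, seed: SeedDefinition,
                         vertex_mask: np.ndarray | None = None) -> np.ndarray:
    """Unweighted mean BOLD series over seed vertices (retained points)."""
    verts = seed.vertex_set
    if verts.max() >= bold.n_vertices:
        raise ValueError("seed vertex index exceeds BOLD vertex count")
    if vertex_mask is not None:
        verts = verts[vertex_mask[verts]]
        if verts.size == 0:
            raise ValueError("seed entirely outside the analysis mask")
    return bold.retained[verts].mean(axis=0)


def seed_fc_map(
    bold: BoldMatrix,
    seed: SeedDefinition,
    mesh: SurfaceMesh,
    fwhm_mm: float = 6.0,
    vertex_mask: np.ndarray | None = None,
) -> FcMap:
    """Fisher-z map of seed-to-vertex correlation, smoothed on the mesh.

    Seed vertices are excluded (their correlation with the seed mean is
    inflated by construction); |r| = 1 elsewhere is capped just below 1
    with a warning before atanh.
    """
    s = seed_mean_timeseries(bold, seed, vertex_mask)
    x = bold.retained
    s0 = s - s.mean()
    sn = np.linalg.norm(s0)
    if sn == 0:
        raise ValueError("constant seed series")
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xc, axis=1)
    ok = norms > 0
    if vertex_mask is not None:
        ok &= vertex_mask
    r = np.zeros(bold.n_vertices)
    r[ok] = (xc[ok] @ s0) / (norms[ok] * sn)
    outside = np.ones(bold.n_vertices, dtype=bool)
    outside[seed.vertex_set] = False
    if np.any(np.abs(r[ok & outside]) >= 1.0):
        warnings.warn("|r| = 1 outside seed; capping before atanh",
                      stacklevel=2)
    z = np.arctanh(np.clip(r, -_R_CAP, _R_CAP))
    z[~ok] = np.nan
    z[seed.vertex_set] = np.nan
    cmap = geodesic_smooth(CorticalMap(values=z, name="seed_fc", units="z"),
                           mesh, fwhm_mm)
    return FcMap(z_values=cmap.values, seed=seed, subject_id=bold.subject_id,
                 smoothing_fwhm_mm=fwhm_mm)


def group_positive_mask(
    fc_maps_by_group: dict[str, np.ndarray],
    alpha: float = 0.001,
    combine: str = "union",
) -> np.ndarray:
    """Vertices with significantly positive FC in either group.

    Per group, a one-sided one-sample t-test of the Fisher-z values against
    zero at vertexwise ``alpha``; zero-variance vertices are excluded.  The
    group masks are combined by union (default) or intersection.
    """
    if combine not in ("union", "intersection"):
        raise ValueError("combine must be 'union' or 'intersection'")
    masks = []
    for name, Z in fc_maps_by_group.items():
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[0] < 2:
            raise ValueError(f"group {name!r} needs >= 2 subjects")
        valid = np.isfinite(Z).all(axis=0) & (Z.std(axis=0) > 0)
        t = np.zeros(Z.shape[1])
        p = np.ones(Z.shape[1])
        with np.errstate(invalid="ignore"):
            tt = stats.ttest_1samp(Z[:, valid], 0.0, alternative="greater")
        t[valid], p[valid] = tt.statistic, tt.pvalue
        masks.append(valid & (p < alpha))
    out = masks[0]
    for m in masks[1:]:
        out = (out | m) if combine == "union" else (out & m)
    return out


def seed_signal_intensity_check(
    raw_bold: dict[str, BoldMatrix],
    seed: SeedDefinition,
    cohort: pd.DataFrame,
    spec: GlmSpec,
) -> pd.DataFrame:
    """Group / interaction effects on raw seed-region signal intensity.

    Uses pre-residualization intensities: per subject, the mean raw signal
    over seed vertices and retained volumes, regressed on the same design as
    the main analysis.  Returns one row per tested term with F and p.
    """
    ids = cohort["id"].astype(str).tolist()
    missing = [i for i in ids if i not in raw_bold]
    if missing:
        raise ValueError(f"raw BOLD missing for subjects: {missing[:5]}")
    intensity = np.array([
        raw_bold[i].retained[seed.vertex_set].mean() for i in ids
    ])
    if intensity.std() == 0:
        raise ValueError("zero variance in seed mean intensity")
    rows = []
    for term in spec.terms:
        one = GlmSpec(terms=spec.terms, contrast=term,
                      covariates=spec.covariates)
        X, cols = build_design(cohort, one)
        res = fit_vertexwise_glm(intensity[:, None], X, cols)
        rows.append({"term": term, "f": float(res.f[0]),
                     "p": float(res.p[0]), "df1": res.df1, "df2": res.df2})
    return pd.DataFrame(rows)
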