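"""Hierarchical multiple-comparison correction on the cortical surface.

Stage 1 controls the family-wise error rate at cluster level: vertexwise
statistics computed from smoothed maps are thresholded (p < 0.001 by
default), suprathreshold vertices are grouped into connected components on
the mesh, and each component's extent — measured in resels, i.e. surface
area divided by the squared effective FWHM estimated from the model
residuals — receives a cluster p-value from the 2-D Gaussian random-field
expected-cluster formulas (the F map is Gaussianized through its p-values
first).  Stage 2 controls the false discovery rate within each surviving
cluster by Benjamini-Hochberg over the *unsmoothed* vertex p-values.

A label-permutation (Freedman-Lane) test over the max cluster extent is
provided both as a validation oracle and as a runtime alternative
(``method="permutation"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

from ..surface import SurfaceMesh, adjacency_matrix
from .glm import VertexGlmResult, fit_vertexwise_glm

__all__ = ["ClusterFinding", "hierarchical_correction",
           "estimate_smoothness_fwhm", "gaussian_cluster_pvalue",
           "permutation_max_extent"]

_4LN2 = 4.0 * np.log(2.0)


@dataclass
class ClusterFinding:
    """One surviving cluster of the hierarchical correction."""

    vertex_set: np.ndarray
    peak_vertex: int
    peak_coords: np.ndarray
    f_stat: float
    df: tuple[int, int]
    p_cluster_fwe: float
    vertex_q_values: np.ndarray
    extent_mm2: float
    contrast: str = ""
    r_squared: float = np.nan
    effect_size: float = np.nan
    effect_size_kind: str = ""
    ci95_low: float = np.nan
    ci95_high: float = np.nan
    bf10: float = np.nan
    evidence_label: str = ""

    def __post_init__(self) -> None:
        self.vertex_set = np.asarray(self.vertex_set, dtype=np.int64)
        if self.peak_vertex not in self.vertex_set:
            raise ValueError("peak vertex must belong to the cluster")


def estimate_smoothness_fwhm(
    residuals: np.ndarray, mesh: SurfaceMesh, mask: np.ndarray | None = None
) -> float:
    """Effective Gaussian FWHM (mm) of the residual field.

    Residual maps are unit-normalized per vertex across subjects; for a
    Gaussian autocorrelation the expected squared edge difference of the
    normalized field is ``h^2 / (2 sigma^2)`` at edge length h, giving
    ``sigma^2 = h^2 / (2 <(du)^2 / h^2>)`` and FWHM = sqrt(8 ln 2) sigma.
    """
    R = np.atleast_2d(np.asarray(residuals, dtype=float))
    n_vert = R.shape[1]
    if mask is None:
        mask = np.isfinite(R).all(axis=0)
    norm = np.sqrt(np.nansum(R ** 2, axis=0))
    ok = mask & (norm > 0)
    U = np.where(ok, R / np.where(norm > 0, norm, 1.0), np.nan)
    e = mesh.edges
    keep = ok[e[:, 0]] & ok[e[:, 1]]
    if not keep.any():
        raise ValueError("no usable edges for smoothness estimation")
    e = e[keep]
    h2 = ((mesh.vertex_coords[e[:, 0]] - mesh.vertex_coords[e[:, 1]]) ** 2
          ).sum(axis=1)
    du2 = ((U[:, e[:, 0]] - U[:, e[:, 1]]) ** 2).sum(axis=0)
    grad2 = (du2 / h2).mean()
    if grad2 <= 0:
        raise ValueError("degenerate residual field (zero gradient)")
    sigma2 = 1.0 / (2.0 * grad2)
    return float(np.sqrt(8.0 * np.log(2.0) * sigma2))


def gaussian_cluster_pvalue(
    extent_resels: float, resels_total: float, z_threshold: float
) -> float:
    """Cluster-level FWE p for a 2-D Gaussian field.

    Expected cluster count E[m] = R * rho2(u) with the 2-D EC density
    rho2(u) = 4 ln2 (2 pi)^(-3/2) u exp(-u^2/2); expected suprathreshold
    volume E[N] = R * Phi(-u); cluster extents are taken exponential with
    rate beta = E[m]/E[N], and the max-cluster p is
    1 - exp(-E[m] * exp(-beta * k)).
    """
    u = z_threshold
    rho2 = _4LN2 * (2.0 * np.pi) ** -1.5 * u * np.exp(-0.5 * u * u)
    e_m = resels_total * rho2
    e_n = resels_total * stats.norm.sf(u)
    if e_n <= 0 or e_m <= 0:
        return 1.0
    beta = e_m / e_n
    return float(-np.expm1(-e_m * np.exp(-beta * extent_resels)))


def _clusters_on_mesh(
    supra: np.ndarray, mesh: SurfaceMesh
) -> list[np.ndarray]:
    idx = np.flatnonzero(supra)
    if len(idx) == 0:
        return []
    sub = adjacency_matrix(mesh)[idx][:, idx]
    n, labels = connected_components(sub, directed=False)
    return [idx[labels == i] for i in range(n)]


def hierarchical_correction(
    smoothed: VertexGlmResult,
    unsmoothed: VertexGlmResult,
    mesh: SurfaceMesh,
    p_vertex: float = 0.001,
    p_cluster: float = 0.05,
    q_fdr: float = 0.05,
    method: str = "rft",
    analysis_mask: np.ndarray | None = None,
    design: pd.DataFrame | None = None,
    maps_smoothed: np.ndarray | None = None,
    contrast_columns: list[str] | None = None,
    n_permutations: int = 500,
    seed: int | None = None,
) -> list[ClusterFinding]:
    """Two-stage correction: cluster FWE (RFT or permutation) then
    within-cluster vertex FDR over unsmoothed p-values.

    Returns findings with ``p_cluster_fwe <= p_cluster``, each carrying
    BH q-values for its member vertices.  An empty list (no suprathreshold
    vertex or no surviving cluster) is a valid outcome, not an error.
    """
    if not (0 < p_vertex < 1 and 0 < p_cluster < 1 and 0 < q_fdr < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    if analysis_mask is None:
        analysis_mask = np.isfinite(smoothed.p)
    supra = analysis_mask & (smoothed.p < p_vertex)
    clusters = _clusters_on_mesh(supra, mesh)
    if not clusters:
        return []

    areas = mesh.vertex_areas
    fwhm = estimate_smoothness_fwhm(smoothed.residuals, mesh, analysis_mask)
    resel_area = fwhm * fwhm
    total_resels = areas[analysis_mask].sum() / resel_area
    z_u = stats.norm.isf(p_vertex)

    if method == "permutation":
        if design is None or maps_smoothed is None or contrast_columns is None:
            raise ValueError(
                "permutation method needs design, maps_smoothed and "
                "contrast_columns"
            )
        null_max = permutation_max_extent(
            maps_smoothed, design, contrast_columns, mesh,
            p_vertex=p_vertex, analysis_mask=analysis_mask,
            n_permutations=n_permutations, seed=seed,
        )
    findings: list[ClusterFinding] = []
    for verts in clusters:
        extent = float(areas[verts].sum())
        if method == "rft":
            p_fwe = gaussian_cluster_pvalue(
                extent / resel_area, total_resels, z_u
            )
        elif method == "permutation":
            p_fwe = float(
                (1 + np.sum(null_max >= extent)) / (len(null_max) + 1)
            )
        else:
            raise ValueError(f"unknown method {method!r}")
        if p_fwe > p_cluster:
            continue
        p_unsm = unsmoothed.p[verts]
        fin = np.isfinite(p_unsm)
        q = np.full(len(verts), np.nan)
        if fin.any():
            _, q[fin], _, _ = multipletests(
                p_unsm[fin], alpha=q_fdr, method="fdr_bh"
            )
        peak = int(verts[np.nanargmax(smoothed.f[verts])])
        findings.append(
            ClusterFinding(
                vertex_set=verts,
                peak_vertex=peak,
                peak_coords=mesh.vertex_coords[peak],
                f_stat=float(smoothed.f[peak]),
                df=(smoothed.df1, smoothed.df2),
                p_cluster_fwe=p_fwe,
                vertex_q_values=q,
                extent_mm2=extent,
                contrast=smoothed.contrast,
                r_squared=float(smoothed.r_squared[peak]),
            )
        )
    findings.sort(key=lambda c: c.p_cluster_fwe)
    return findings


def permutation_max_extent(
    maps_smoothed: np.ndarray,
    design: pd.DataFrame,
    contrast_columns: list[str],
    mesh: SurfaceMesh,
    p_vertex: float = 0.001,
    analysis_mask: np.ndarray | None = None,
    n_permutations: int = 500,
    seed: int | None = None,
) -> np.ndarray:
    """Null distribution of the maximal suprathreshold cluster area (mm^2)
    under Freedman-Lane permutation of reduced-model residuals."""
    rng = np.random.default_rng(seed)
    Y = np.asarray(maps_smoothed, dtype=float)
    keep = [c for c in design.columns if c not in contrast_columns]
    Xr = design[keep].to_numpy(dtype=float)
    Qr, _ = np.linalg.qr(Xr)
    fit_r = Qr @ (Qr.T @ np.nan_to_num(Y))
    resid_r = np.nan_to_num(Y) - fit_r
    areas = mesh.vertex_areas
    if analysis_mask is None:
        analysis_mask = np.isfinite(Y).all(axis=0)
    out = np.zeros(n_permutations)
    n = Y.shape[0]
    for b in range(n_permutations):
        perm = rng.permutation(n)
        Yb = fit_r + resid_r[perm]
        res = fit_vertexwise_glm(Yb, design, contrast_columns)
        supra = analysis_mask & (res.p < p_vertex)
        clusters = _clusters_on_mesh(supra, mesh)
        out[b] = max((areas[c].sum() for c in clusters), default=0.0)
    return out


_TABLE_COLUMNS = [
    "contrast", "peak_vertex", "peak_x_mm", "peak_y_mm", "peak_z_mm",
    "n_vertices", "extent_mm2", "r_squared", "f", "df1", "df2",
    "p_cluster_fwe", "effect_size", "effect_size_kind", "ci95_low",
    "ci95_high", "bf10", "evidence",
]


def findings_table(findings: list[ClusterFinding]) -> pd.DataFrame:
    """Flatten findings into a report table (one row per cluster)."""
    if not findings:
        return pd.DataFrame(columns=_TABLE_COLUMNS)
    rows = []
    for c in findings:
        rows.append({
            "contrast": c.contrast,
            "peak_vertex": c.peak_vertex,
            "peak_x_mm": c.peak_coords[0],
            "peak_y_mm": c.peak_coords[1],
            "peak_z_mm": c.peak_coords[2],
            "n_vertices": len(c.vertex_set),
            "extent_mm2": c.extent_mm2,
            "r_squared": c.r_squared,
            "f": c.f_stat,
            "df1": c.df[0],
            "df2": c.df[1],
            "p_cluster_fwe": c.p_cluster_fwe,
            "effect_size": c.effect_size,
            "effect_size_kind": c.effect_size_kind,
            "ci95_low": c.ci95_low,
            "ci95_high": c.ci95_high,
            "bf10": c.bf10,
            "evidence": c.evidence_label,
        })
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)
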