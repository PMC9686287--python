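"""Vertexwise general linear models.

A single design matrix is shared by all vertices; the outcome is a subjects x
vertices stack of cortical maps (or a scalar per subject for cognition
models).  Inference on a named term is an extra-sum-of-squares F test of the
full design against the design with that term's columns removed, computed in
one vectorized pass.  Continuous moderators are mean-centered before
interactions are formed, and collinearity is monitored with variance
inflation factors (flagged at VIF >= 10).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = ["GlmSpec", "build_design", "fit_vertexwise_glm", "vif_check",
           "VertexGlmResult"]

F_CAP = 1e12


@dataclass
class GlmSpec:
    """Declarative description of a vertexwise model.

    ``terms`` are the predictors of interest (e.g. ``["group"]`` or
    ``["group", "sex", "group:sex"]``); ``contrast`` names the term whose
    extra-sum-of-squares F test is reported.  ``covariates`` are adjusted
    for but not tested.  Interaction terms use ``a:b`` syntax; continuous
    components are centered before multiplication.
    """

    terms: list[str]
    contrast: str
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.contrast not in self.terms:
            raise ValueError(
                f"contrast {self.contrast!r} not among terms {self.terms}"
            )


def _centered(col: pd.Series) -> np.ndarray:
    x = col.to_numpy(dtype=float)
    if col.nunique() > 2:
        return x - x.mean()
    return x


def build_design(
    cohort: pd.DataFrame, spec: GlmSpec
) -> tuple[pd.DataFrame, list[str]]:
    """Build the design matrix for a spec; returns (X, contrast columns).

    Output columns: intercept, covariates, main terms, interactions.  Binary
    columns enter as 0/1; continuous columns are centered (so interactions
    with them are formed from centered factors).
    """
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(cohort))}
    for name in spec.covariates + [t for t in spec.terms if ":" not in t]:
        if name in cols:
            continue
        if name not in cohort.columns:
            raise KeyError(f"column {name!r} missing from cohort table")
        cols[name] = _centered(cohort[name])
    for term in spec.terms:
        if ":" not in term:
            continue
        parts = term.split(":")
        prod = np.ones(len(cohort))
        for p in parts:
            if p not in cohort.columns:
                raise KeyError(f"column {p!r} missing from cohort table")
            prod = prod * _centered(cohort[p])
        cols[term] = prod
    X = pd.DataFrame(cols, index=cohort.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = np.corrcoef(X.to_numpy()[:, 1:], rowvar=False)
        np.fill_diagonal(corr, 0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        names = list(X.columns[1:])
        raise ValueError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); "
            f"most collinear pair: {names[i]!r}, {names[j]!r}"
        )
    return X, [spec.contrast]


@dataclass
class VertexGlmResult:
    """Per-vertex F statistics for a named contrast."""

    f: np.ndarray
    p: np.ndarray
    df1: int
    df2: int
    residuals: np.ndarray          # subjects x vertices, full-model residuals
    r_squared: np.ndarray
    contrast: str
    beta: np.ndarray               # p x vertices
    columns: list[str]


def fit_vertexwise_glm(
    maps: np.ndarray,
    X: pd.DataFrame,
    contrast_columns: list[str],
    contrast_name: str | None = None,
) -> VertexGlmResult:
    """Vectorized OLS + extra-sum-of-squares F test at every vertex.

    ``maps``: subjects x vertices (columns that contain NaN are skipped and
    reported as NaN statistics).
    """
    Y = np.atleast_2d(np.asarray(maps, dtype=float))
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError(f"maps have {Y.shape[0]} rows but design has {n}")
    if n < p + 2:
        raise ValueError(f"need >= {p + 2} subjects for {p} predictors")
    missing = [c for c in contrast_columns if c not in X.columns]
    if missing:
        raise KeyError(f"contrast columns not in design: {missing}")
    Xf = X.to_numpy(dtype=float)
    keep = [c for c in X.columns if c not in contrast_columns]
    Xr = X[keep].to_numpy(dtype=float)
    q = p - Xr.shape[1]

    good = np.isfinite(Y).all(axis=0)
    Yg = Y[:, good]

    Qf, _ = np.linalg.qr(Xf)
    Qr, _ = np.linalg.qr(Xr)
    fit_f = Qf @ (Qf.T @ Yg)
    fit_r = Qr @ (Qr.T @ Yg)
    resid_f = Yg - fit_f
    ssr_f = (resid_f ** 2).sum(axis=0)
    ssr_r = ((Yg - fit_r) ** 2).sum(axis=0)
    df2 = n - p
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(
            ssr_f > 0,
            ((ssr_r - ssr_f) / q) / (ssr_f / df2),
            np.where(ssr_r > ssr_f, F_CAP, 0.0),
        )
    f = np.clip(f, 0.0, F_CAP)
    pval = stats.f.sf(f, q, df2)
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    tss = ((Yg - Yg.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(tss > 0, 1.0 - ssr_f / tss, 0.0)
    beta_g, *_ = np.linalg.lstsq(Xf, Yg, rcond=None)

    def _expand(a: np.ndarray, fill=np.nan) -> np.ndarray:
        out = np.full(Y.shape[1], fill)
        out[good] = a
        return out

    resid = np.full(Y.shape, np.nan)
    resid[:, good] = resid_f
    beta = np.full((p, Y.shape[1]), np.nan)
    beta[:, good] = beta_g
    return VertexGlmResult(
        f=_expand(f), p=_expand(pval), df1=q, df2=df2, residuals=resid,
        r_squared=_expand(r2),
        contrast=contrast_name or "+".join(contrast_columns),
        beta=beta, columns=list(X.columns),
    )


def vif_check(X: pd.DataFrame, threshold: float = 10.0) -> pd.Series:
    """Variance inflation factor per non-intercept column; warn at >= 10."""
    cols = [c for c in X.columns if c != "intercept"]
    arr = X.to_numpy(dtype=float)
    idx = [list(X.columns).index(c) for c in cols]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        vifs = pd.Series(
            [variance_inflation_factor(arr, i) for i in idx], index=cols
        )
    high = vifs[vifs >= threshold]
    if len(high):
        warnings.warn(
            f"VIF >= {threshold} for: {', '.join(high.index)}", stacklevel=2
        )
    return vifs
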