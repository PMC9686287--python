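"""Cognition moderation models.

Tests whether a cluster-mean connectivity measure is associated with a
neuropsychological score as a function of group (and optionally sex or
insulin resistance), adjusting for the standard covariate set.  Scores are
Yeo-Johnson transformed first (timing-based scores are sign-flipped so that
higher always means better), the measure x moderator interaction is tested
with an extra-sum-of-squares F, and the alternative hypothesis is accepted
only under the triple criterion: frequentist p < 0.05, JZS BF10 >= 3, and a
BCa 95% CI for the standardized interaction effect excluding zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .bayes import jzs_bf10
from .effects import bca_bootstrap_ci
from .glm import GlmSpec, build_design, fit_vertexwise_glm

__all__ = ["yeo_johnson", "cognition_moderation", "CognitionResult"]


def yeo_johnson(values, lmbda="mle"):
    """Yeo-Johnson power transform; returns (transformed, lambda).

    ``lmbda="mle"`` profiles the normal log-likelihood for the optimal
    lambda; a numeric lambda is applied directly (lambda = 1 is the
    identity).
    """
    x = np.asarray(values, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    if isinstance(lmbda, str):
        if lmbda != "mle":
            raise ValueError("lmbda must be a number or 'mle'")
        out, lam = sps.yeojohnson(x)
        return out, float(lam)
    return sps.yeojohnson(x, lmbda=float(lmbda)), float(lmbda)


@dataclass
class CognitionResult:
    contrast: str
    f: float
    p: float
    df: tuple[int, int]
    r_squared: float
    bf10: float
    evidence_label: str
    effect_size: float
    ci95: tuple[float, float]
    valid: bool
    yj_lambda: float
    simple_slopes: dict[str, float] = field(default_factory=dict)


def _standardized_coef(y, X: pd.DataFrame, term: str) -> float:
    beta, *_ = np.linalg.lstsq(X.to_numpy(float), np.asarray(y, float),
                               rcond=None)
    resid = np.asarray(y, float) - X.to_numpy(float) @ beta
    sd_res = resid.std(ddof=X.shape[1])
    if sd_res == 0:
        return 0.0
    j = list(X.columns).index(term)
    return float(beta[j] * X[term].to_numpy().std(ddof=1) / sd_res)


def cognition_moderation(
    measure: np.ndarray,
    score: np.ndarray,
    cohort: pd.DataFrame,
    moderators: list[str],
    covariates: list[str],
    higher_is_worse: bool = False,
    n_boot: int = 2000,
    seed: int | None = None,
) -> CognitionResult:
    """Moderated association between a cluster-mean measure and cognition.

    ``moderators`` is ``["group"]``, ``["group", "sex_code"]`` or
    ``["group", "homa"]``; the tested contrast is the highest-order
    measure x moderator interaction.
    """
    if not moderators:
        raise ValueError("at least one moderator required")
    df = cohort.copy()
    raw = -np.asarray(score, float) if higher_is_worse else np.asarray(
        score, float)
    y, lam = yeo_johnson(sps.zscore(raw))
    df["_measure"] = np.asarray(measure, float)

    for m in moderators:
        if df[m].nunique() < 2:
            raise ValueError(f"moderator {m!r} has a single level")
        if df[m].nunique() == 2:
            for level, sub in df.groupby(m):
                if len(sub) < 3:
                    raise ValueError(f"subgroup {m}={level} too small")

    # full factorial in measure and moderators
    factors = ["_measure"] + list(moderators)
    terms: list[str] = []
    for size in range(1, len(factors) + 1):
        for combo in combinations(factors, size):
            terms.append(":".join(combo))
    contrast = ":".join(factors)
    spec = GlmSpec(terms=terms, contrast=contrast,
                   covariates=[c for c in covariates if c not in moderators])
    X, _ = build_design(df, spec)
    res = fit_vertexwise_glm(y[:, None], X, [contrast])
    f, p = float(res.f[0]), float(res.p[0])

    X_null = X.drop(columns=[contrast])
    bf10, label = jzs_bf10(y, X_null, X)

    def _stat(d: pd.DataFrame) -> float:
        return _standardized_coef(d["_y"].to_numpy(), d[X.columns], contrast)

    boot_df = X.copy()
    boot_df["_y"] = y
    ci = bca_bootstrap_ci(_stat, boot_df, n_boot=n_boot, seed=seed)
    eff = _standardized_coef(y, X, contrast)
    valid = (p < 0.05) and (bf10 >= 3.0) and (ci[0] > 0 or ci[1] < 0)

    slopes = _simple_slopes(df, y, moderators)
    return CognitionResult(
        contrast=contrast, f=f, p=p, df=(res.df1, res.df2),
        r_squared=float(res.r_squared[0]), bf10=bf10, evidence_label=label,
        effect_size=eff, ci95=ci, valid=valid, yj_lambda=lam,
        simple_slopes=slopes,
    )


def _simple_slopes(df: pd.DataFrame, y: np.ndarray,
                   moderators: list[str]) -> dict[str, float]:
    """Within-cell OLS slope of the transformed score on the measure; cells
    are defined by the binary moderators (continuous ones held at mean)."""
    cats = [m for m in moderators if df[m].nunique() == 2]
    slopes: dict[str, float] = {}
    cells = df.groupby(cats).groups.items() if cats else [("all", df.index)]
    for key, idx in cells:
        sub = df.loc[idx]
        x = sub["_measure"].to_numpy(float)
        if x.std() == 0 or len(sub) < 3:
            continue
        yy = y[df.index.get_indexer(idx)]
        slope = np.polyfit(x, yy, 1)[0]
        name = key if isinstance(key, str) else ",".join(
            f"{m}={v}" for m, v in zip(cats, np.atleast_1d(key)))
        slopes[name] = float(slope)
    return slopes
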