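"""Standardized effect sizes and BCa bootstrap confidence intervals.

Cohen's d for two-group contrasts at a cluster's peak vertex; a standardized
moderation effect (delta) for continuous-moderator interactions, defined as
the interaction coefficient scaled by the moderator SD (within the exposed
group) over the residual SD; and bias-corrected accelerated (BCa) bootstrap
intervals with the bias correction z0 read off the bootstrap CDF at the point
estimate and the acceleration from jackknife skewness.
"""

from __future__ import annotations

import warnings
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["cohens_d", "effect_size_delta", "bca_bootstrap_ci"]


def cohens_d(group1: np.ndarray, group2: np.ndarray) -> float:
    """(mean1 - mean2) / pooled SD (unbiased variance pooling)."""
    x1 = np.asarray(group1, dtype=float)
    x2 = np.asarray(group2, dtype=float)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    pooled_var = (
        ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1))
        / (n1 + n2 - 2)
    )
    if pooled_var == 0:
        raise ValueError("zero pooled SD")
    return float((x1.mean() - x2.mean()) / np.sqrt(pooled_var))


def effect_size_delta(
    interaction_coef: float,
    moderator_values: np.ndarray,
    residual_sd: float,
) -> float:
    """Standardized moderation effect:
    coefficient * SD(moderator) / SD(residuals)."""
    sd_mod = np.asarray(moderator_values, dtype=float).std(ddof=1)
    if residual_sd <= 0:
        raise ValueError("residual SD must be positive")
    return float(interaction_coef * sd_mod / residual_sd)


def bca_bootstrap_ci(
    statistic: Callable[[np.ndarray | pd.DataFrame], float],
    data: np.ndarray | pd.DataFrame,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """BCa confidence interval for ``statistic`` of row-resampled ``data``.

    The resampling unit is the row (subject).  Deterministic given ``seed``.
    A degenerate bootstrap distribution (all resamples equal) collapses to a
    point interval with a warning.
    """
    if n_boot < 500:
        raise ValueError("n_boot must be >= 500")
    rng = np.random.default_rng(seed)
    is_frame = isinstance(data, pd.DataFrame)
    arr = data if is_frame else np.asarray(data)
    n = len(arr)

    def take(idx: np.ndarray):
        return arr.iloc[idx] if is_frame else arr[idx]

    theta_hat = float(statistic(arr))
    boot = np.empty(n_boot)
    for b in range(n_boot):
        boot[b] = statistic(take(rng.integers(0, n, n)))
    if not np.isfinite(boot).all():
        raise ValueError("statistic non-finite on bootstrap resamples")
    if np.ptp(boot) == 0:
        warnings.warn("degenerate bootstrap distribution; point interval",
                      stacklevel=2)
        return float(boot[0]), float(boot[0])

    # bias correction from the bootstrap CDF at the point estimate
    prop = np.clip(np.mean(boot < theta_hat), 1.0 / (2 * n_boot),
                   1.0 - 1.0 / (2 * n_boot))
    z0 = stats.norm.ppf(prop)
    # acceleration from jackknife skewness
    jack = np.empty(n)
    all_idx = np.arange(n)
    for i in range(n):
        jack[i] = statistic(take(np.delete(all_idx, i)))
    dev = jack.mean() - jack
    denom = (dev ** 2).sum() ** 1.5
    a = (dev ** 3).sum() / (6.0 * denom) if denom > 0 else 0.0

    alpha = (1.0 - level) / 2.0
    out = []
    for a_lev in (alpha, 1.0 - alpha):
        z = z0 + stats.norm.ppf(a_lev)
        adj = stats.norm.cdf(z0 + z / (1.0 - a * z))
        out.append(float(np.quantile(boot, adj)))
    return out[0], out[1]
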