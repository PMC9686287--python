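"""Jeffreys-Zellner-Siow Bayes factors for nested linear models.

The evidence for adding predictors of interest to a covariate-only null
model is quantified with the Zellner-Siow mixture-of-g prior: standardized
regression effects receive a Cauchy prior of scale ``r`` (default 0.354,
the "medium" regression scale), equivalent to g ~ InverseGamma(1/2, n r^2/2).
Each model's marginal likelihood against the intercept-only base is

    B(M_k) = Int_0^inf (1+g)^((n-1-k)/2) [1 + g (1-R_k^2)]^(-(n-1)/2) pi(g) dg

with k non-intercept predictors and coefficient of determination R_k^2;
BF10 = B(full) / B(null).  The one-dimensional integral is evaluated by
adaptive quadrature on the log scale after locating the integrand's mode.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import integrate, optimize

__all__ = ["jzs_bf10", "log_zs_marginal", "bf_evidence_label"]

DEFAULT_R_SCALE = 0.354


def _design_array(X) -> np.ndarray:
    arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(
        X, dtype=float
    )
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def _r_squared(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """(R^2 relative to the intercept-only model, non-intercept rank)."""
    n = len(y)
    ones = np.ones((n, 1))
    has_intercept = np.allclose(
        X @ np.linalg.lstsq(X, ones, rcond=None)[0], ones
    )
    if not has_intercept:
        X = np.hstack([ones, X])
    Q, _ = np.linalg.qr(X)
    resid = y - Q @ (Q.T @ y)
    sst = ((y - y.mean()) ** 2).sum()
    if sst == 0:
        raise ValueError("constant outcome")
    r2 = 1.0 - (resid ** 2).sum() / sst
    k = np.linalg.matrix_rank(X) - 1
    return float(np.clip(r2, 0.0, 1.0 - 1e-12)), int(k)


def _log_integrand(u: np.ndarray, n: int, k: int, r2: float,
                   r_scale: float) -> np.ndarray:
    """Log integrand after substituting g = exp(u) (includes the Jacobian)."""
    g = np.exp(u)
    b = n * r_scale * r_scale / 2.0
    # inverse-gamma(1/2, b) density: b^(1/2) / Gamma(1/2) g^(-3/2) e^(-b/g)
    log_prior = (0.5 * np.log(b) - 0.5 * np.log(np.pi)
                 - 1.5 * np.log(g) - b / g)
    return (
        0.5 * (n - 1 - k) * np.log1p(g)
        - 0.5 * (n - 1) * np.log1p(g * (1.0 - r2))
        + log_prior
        + u                                    # Jacobian dg = g du
    )


def log_zs_marginal(n: int, k: int, r2: float,
                    r_scale: float = DEFAULT_R_SCALE,
                    rtol: float = 1e-8) -> float:
    """log of the Zellner-Siow marginal-likelihood ratio vs intercept-only."""
    if k == 0:
        return 0.0
    mode = optimize.minimize_scalar(
        lambda u: -_log_integrand(np.asarray(u), n, k, r2, r_scale),
        bounds=(-30.0, 30.0), method="bounded",
    ).x
    shift = _log_integrand(np.asarray(mode), n, k, r2, r_scale)
    val, err = integrate.quad(
        lambda u: np.exp(_log_integrand(np.asarray(u), n, k, r2, r_scale)
                         - shift),
        -40.0, 40.0, epsabs=0.0, epsrel=rtol, limit=400,
    )
    if val <= 0 or err / val > 1e-4:
        raise RuntimeError(
            f"quadrature did not converge: value={val:.3e}, "
            f"abs err={err:.3e}, rel err={err / max(val, 1e-300):.3e}"
        )
    return float(shift + np.log(val))


def _check_nested(X_null: np.ndarray, X_full: np.ndarray) -> None:
    Q, _ = np.linalg.qr(X_full)
    resid = X_null - Q @ (Q.T @ X_null)
    scale = max(1.0, np.abs(X_null).max())
    if np.abs(resid).max() > 1e-8 * scale:
        raise ValueError("designs are not nested (null not in full's span)")


def jzs_bf10(
    y,
    X_null,
    X_full,
    r_scale: float = DEFAULT_R_SCALE,
) -> tuple[float, str]:
    """JZS Bayes factor of the full model over the nested null model.

    Both models implicitly contain an intercept; the null may be
    intercept-only.  Returns ``(BF10, evidence_label)``; the conventional
    decision rule reads BF10 >= 3 as at least moderate evidence.
    """
    y = np.asarray(y, dtype=float).ravel()
    Xn = _design_array(X_null)
    Xf = _design_array(X_full)
    if not (len(y) == len(Xn) == len(Xf)):
        raise ValueError("row counts of y and designs differ")
    n = len(y)
    _check_nested(Xn, Xf)
    r2_full, k_full = _r_squared(y, Xf)
    r2_null, k_null = _r_squared(y, Xn)
    if n <= k_full + 1:
        raise ValueError("need n > rank(full design)")
    log_bf = (log_zs_marginal(n, k_full, r2_full, r_scale)
              - log_zs_marginal(n, k_null, r2_null, r_scale))
    bf10 = float(np.exp(log_bf))
    return bf10, bf_evidence_label(bf10)


def bf_evidence_label(bf10: float) -> str:
    """Conventional evidence categories for BF10."""
    if bf10 >= 100:
        return "extreme"
    if bf10 >= 30:
        return "very strong"
    if bf10 >= 10:
        return "strong"
    if bf10 >= 3:
        return "moderate"
    if bf10 > 1:
        return "anecdotal"
    if bf10 == 1:
        return "none"
    return "favors null"
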