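"""Time-series quality control: volume censoring and nuisance regression.

Implements the resting-state cleanup rules applied before connectivity
mapping: outlier-volume detection (a volume is discarded when more than 5% of
vertices deviate from their temporal median by more than k median absolute
deviations), motion censoring at a framewise-displacement cut-off of 0.3 mm,
subject exclusion when more than 20% of volumes are censored, and per-vertex
least-squares nuisance regression (intercept, linear drift, six motion
parameters with first derivatives, mean white-matter/CSF signal,
physiological series with derivatives).  No temporal band-pass filtering is
applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BoldMatrix",
    "NuisanceSet",
    "flag_outlier_volumes",
    "censor_high_motion",
    "subject_passes_qc",
    "nuisance_regress",
    "framewise_displacement",
]

OUTLIER_VERTEX_FRACTION = 0.05
MOTION_THRESHOLD_MM = 0.3
MAX_CENSORED_FRACTION = 0.20


@dataclass
class BoldMatrix:
    """Per-subject vertex x time BOLD data with a retention mask.

    ``censor_mask`` is True at retained time points.
    """

    values: np.ndarray
    tr_seconds: float = 2.0
    censor_mask: np.ndarray | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("BOLD values must be vertex x time (2-D)")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.censor_mask is None:
            self.censor_mask = np.ones(self.n_timepoints, dtype=bool)
        else:
            self.censor_mask = np.asarray(self.censor_mask, dtype=bool)
            if len(self.censor_mask) != self.n_timepoints:
                raise ValueError(
                    f"censor_mask length {len(self.censor_mask)} != "
                    f"time dimension {self.n_timepoints}"
                )
        if self.censor_mask.sum() < 2:
            raise ValueError("fewer than 2 retained time points")

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def retained(self) -> np.ndarray:
        """values restricted to retained time points (vertex x t_retained)."""
        return self.values[:, self.censor_mask]

    def censored_fraction(self) -> float:
        return 1.0 - self.censor_mask.mean()


@dataclass
class NuisanceSet:
    """Confound series sharing the BOLD time axis.

    Derivatives are backward first differences with the first element 0.
    """

    motion6: np.ndarray                      # (T, 6)
    tissue_signals: np.ndarray               # (T, k) WM/CSF means
    physio: np.ndarray                       # (T, k) pulse/respiration
    motion6_deriv: np.ndarray | None = None
    physio_deriv: np.ndarray | None = None
    framewise_displacement_mm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.motion6 = np.atleast_2d(np.asarray(self.motion6, float))
        self.tissue_signals = np.atleast_2d(np.asarray(self.tissue_signals, float))
        self.physio = np.atleast_2d(np.asarray(self.physio, float))
        T = self.motion6.shape[0]
        if self.motion6.shape[1] != 6:
            raise ValueError("motion6 must have 6 columns")
        for arr_name in ("tissue_signals", "physio"):
            if getattr(self, arr_name).shape[0] != T:
                raise ValueError(f"{arr_name} length mismatch with motion6")
        if self.motion6_deriv is None:
            self.motion6_deriv = _first_difference(self.motion6)
        if self.physio_deriv is None:
            self.physio_deriv = _first_difference(self.physio)
        if self.framewise_displacement_mm is None:
            self.framewise_displacement_mm = framewise_displacement(self.motion6)

    @property
    def n_timepoints(self) -> int:
        return self.motion6.shape[0]

    def design_columns(self) -> tuple[np.ndarray, list[str]]:
        """Named nuisance regressors (without intercept/drift)."""
        blocks = [
            (self.motion6, [f"motion{i}" for i in range(6)]),
            (self.motion6_deriv, [f"motion{i}_d" for i in range(6)]),
            (self.tissue_signals,
             [f"tissue{i}" for i in range(self.tissue_signals.shape[1])]),
            (self.physio, [f"physio{i}" for i in range(self.physio.shape[1])]),
            (self.physio_deriv,
             [f"physio{i}_d" for i in range(self.physio.shape[1])]),
        ]
        cols = np.hstack([b for b, _ in blocks])
        names = [n for _, ns in blocks for n in ns]
        return cols, names

    def to_frame(self) -> pd.DataFrame:
        cols, names = self.design_columns()
        df = pd.DataFrame(cols, columns=names)
        df["framewise_displacement_mm"] = self.framewise_displacement_mm
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NuisanceSet":
        motion = df[[f"motion{i}" for i in range(6)]].to_numpy()
        tissue = df[[c for c in df.columns if c.startswith("tissue")]].to_numpy()
        physio = df[[c for c in df.columns
                     if c.startswith("physio") and not c.endswith("_d")]].to_numpy()
        fd = (df["framewise_displacement_mm"].to_numpy()
              if "framewise_displacement_mm" in df else None)
        return cls(motion6=motion, tissue_signals=tissue, physio=physio,
                   framewise_displacement_mm=fd)


def _first_difference(x: np.ndarray) -> np.ndarray:
    d = np.diff(x, axis=0, prepend=x[:1])
    return d


def framewise_displacement(
    motion6: np.ndarray, rotation_radius_mm: float = 50.0
) -> np.ndarray:
    """FD as the sum of absolute backward differences of the six rigid-body
    parameters, rotations (assumed radians, columns 3:6) converted to arc
    length on a 50 mm sphere.  First element is 0.
    """
    motion6 = np.atleast_2d(np.asarray(motion6, float))
    d = np.abs(_first_difference(motion6))
    d[:, 3:6] *= rotation_radius_mm
    return d.sum(axis=1)


def flag_outlier_volumes(
    bold: BoldMatrix,
    mad_multiplier: float | None = None,
    vertex_fraction: float = OUTLIER_VERTEX_FRACTION,
    per_vertex: bool = True,
) -> np.ndarray:
    """Boolean flag per time point; True marks an outlier volume.

    A volume is an outlier when the fraction of vertices whose absolute
    deviation from their temporal median exceeds ``mad_multiplier`` times the
    (per-vertex, or global when ``per_vertex=False``) MAD is above
    ``vertex_fraction``.  Vertices with zero MAD are excluded from the
    fraction's denominator.

    The default multiplier is the detection rule of the standard outlier
    counter for T volumes, ``Phi^-1(1 - 0.001/T) * sqrt(pi/2)`` (about 5.6
    at T = 250).  A multiplier of exactly 1 — "beyond one MAD" read
    literally — is degenerate for any continuous-valued series, since half
    of every vertex's samples exceed its own MAD by definition, flagging
    every volume; pass it explicitly if that literal rule is wanted.
    """
    if bold.n_timepoints < 2:
        raise ValueError("need at least 2 time points")
    if mad_multiplier is None:
        from scipy.stats import norm
        mad_multiplier = float(
            norm.isf(0.001 / bold.n_timepoints) * np.sqrt(np.pi / 2.0))
    x = bold.values
    med = np.median(x, axis=1, keepdims=True)
    dev = np.abs(x - med)
    mad = np.median(dev, axis=1, keepdims=True)
    if not per_vertex:
        mad = np.full_like(mad, np.median(mad))
    valid = (mad > 0).ravel()
    if not valid.any():
        return np.zeros(bold.n_timepoints, dtype=bool)
    exceed = dev[valid] > mad_multiplier * mad[valid]
    frac = exceed.mean(axis=0)
    return frac > vertex_fraction


def censor_high_motion(
    nuisance: NuisanceSet, threshold_mm: float = MOTION_THRESHOLD_MM
) -> np.ndarray:
    """Boolean flag per time point; True marks displacement strictly > cut-off."""
    if threshold_mm < 0:
        raise ValueError("threshold_mm must be non-negative")
    fd = nuisance.framewise_displacement_mm
    if fd is None:
        raise ValueError("framewise displacement unavailable")
    return fd > threshold_mm


def subject_passes_qc(
    censor_mask: np.ndarray, max_fraction: float = MAX_CENSORED_FRACTION
) -> bool:
    """True unless strictly more than ``max_fraction`` of volumes were censored."""
    censor_mask = np.asarray(censor_mask, dtype=bool)
    censored = 1.0 - censor_mask.mean()
    return not censored > max_fraction


def apply_censoring(bold: BoldMatrix, outlier_flags: np.ndarray,
                    motion_flags: np.ndarray) -> BoldMatrix:
    """Conjoin flags into the retention mask (order of the two rules is
    immaterial: the final mask is the AND of their complements)."""
    keep = bold.censor_mask & ~np.asarray(outlier_flags) & ~np.asarray(motion_flags)
    return BoldMatrix(values=bold.values, tr_seconds=bold.tr_seconds,
                      censor_mask=keep, subject_id=bold.subject_id)


def nuisance_regress(bold: BoldMatrix, nuisance: NuisanceSet) -> BoldMatrix:
    """Per-vertex OLS residualization over retained time points.

    Design: intercept, linear drift, motion (6) + derivatives, tissue means,
    physiological series + derivatives.  Residuals are orthogonal to every
    regressor; censored-out time points are zero-filled in the output and
    remain flagged.  No frequency filtering is performed.
    """
    if nuisance.n_timepoints != bold.n_timepoints:
        raise ValueError("nuisance and BOLD time dimensions differ")
    keep = bold.censor_mask
    cols, names = nuisance.design_columns()
    T = int(keep.sum())
    drift = np.linspace(-1.0, 1.0, bold.n_timepoints)[keep]
    X = np.column_stack([np.ones(T), drift, cols[keep]])
    names = ["intercept", "drift"] + names
    if T <= X.shape[1]:
        raise ValueError(
            f"retained time points ({T}) must exceed regressors ({X.shape[1]})"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X, names)
        raise ValueError(f"rank-deficient nuisance design; collinear: {bad}")
    Y = bold.values[:, keep].T                      # T x V
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = np.zeros_like(bold.values)
    out[:, keep] = resid.T
    return BoldMatrix(values=out, tr_seconds=bold.tr_seconds,
                      censor_mask=keep.copy(), subject_id=bold.subject_id)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [names[i] for i in np.flatnonzero(diag < tol)]
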