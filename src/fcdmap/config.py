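"""Run configuration: analysis constants, paths, seeds, stage toggles."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

__all__ = ["RunConfig", "validate_config"]

COVARIATES = ["age", "sex_code", "education", "bmi", "homa", "al_ratio",
              "ms", "crf"]


@dataclass
class RunConfig:
    """All analysis constants in one declarative object.

    Defaults are the study's printed constants: correlation threshold
    R > 0.6, 6 mm FWHM smoothing, vertexwise p < 0.001 with cluster
    p(FWE) < 0.05 and within-cluster FDR q < 0.05, JZS r-scale 0.354,
    motion censor 0.3 mm, 5% outlier-vertex fraction, 20% subject
    exclusion.
    """

    out_dir: str = "fcd_run"
    threshold_r: float = 0.6
    fwhm_mm: float = 6.0
    p_vertex: float = 0.001
    p_cluster: float = 0.05
    q_fdr: float = 0.05
    bf_r_scale: float = 0.354
    motion_threshold_mm: float = 0.3
    outlier_fraction: float = 0.05
    exclusion_fraction: float = 0.20
    correction_method: str = "rft"          # or "permutation"
    seed: int = 0
    # simulation settings
    n_subjects: int = 144
    n_prediabetes: int = 71
    n_female: int = 79
    mesh_subdivisions: int = 3
    n_patches: int = 24
    n_timepoints: int = 250
    tr_seconds: float = 2.0
    n_boot: int = 2000
    # stage toggles
    run_qc: bool = True
    run_fcd: bool = True
    run_stats: bool = True
    run_seedfc: bool = True
    run_cognition: bool = True

    def to_json(self, path: str | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def validate_config(config: RunConfig) -> list[str]:
    """Return every range/consistency violation (empty list = clean)."""
    errors: list[str] = []
    c = config
    if not (0 < c.threshold_r < 1):
        errors.append(f"threshold_r out of (0,1): {c.threshold_r}")
    if c.fwhm_mm < 0:
        errors.append(f"fwhm_mm negative: {c.fwhm_mm}")
    for name in ("p_vertex", "p_cluster", "q_fdr"):
        v = getattr(c, name)
        if not (0 < v < 1):
            errors.append(f"{name} out of (0,1): {v}")
    if c.bf_r_scale <= 0:
        errors.append(f"bf_r_scale must be positive: {c.bf_r_scale}")
    if c.motion_threshold_mm < 0:
        errors.append(f"motion_threshold_mm negative: {c.motion_threshold_mm}")
    for name in ("outlier_fraction", "exclusion_fraction"):
        v = getattr(c, name)
        if not (0 < v < 1):
            errors.append(f"{name} out of (0,1): {v}")
    if c.correction_method not in ("rft", "permutation"):
        errors.append(f"correction_method unknown: {c.correction_method}")
    if not (0 <= c.n_prediabetes <= c.n_subjects
            and 0 <= c.n_female <= c.n_subjects):
        errors.append("cohort counts infeasible")
    if c.n_timepoints < 3:
        errors.append("n_timepoints must be >= 3")
    if c.mesh_subdivisions < 0:
        errors.append("mesh_subdivisions must be >= 0")
    return errors
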