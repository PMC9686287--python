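"""Cardiometabolic scalar estimators.

HOMA insulin-resistance index, insulin unit conversion, a non-exercise
cardiorespiratory-fitness (CRF) equation, a continuous metabolic-syndrome
(MS) severity score, adiponectin/leptin ratio, and fasting-glucose glycemia
classification (normoglycemia < 5.6 mmol/l, pre-diabetes 5.6-6.9 inclusive,
> 6.9 excluded as the diabetes range).
"""

from __future__ import annotations

import warnings
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

__all__ = [
    "homa",
    "insulin_si_to_conventional",
    "crf",
    "ms_score",
    "classify_glycemia",
    "al_ratio",
    "add_derived_columns",
    "round_half_up",
]

HDL_MMOL_TO_MG_DL = 38.67
GLYCEMIA_LOWER_MMOL = 5.6
GLYCEMIA_UPPER_MMOL = 6.9


def homa(insulin_mU_per_l, glucose_mmol_per_l):
    """HOMA-IR = fasting insulin (mU/l) x fasting glucose (mmol/l) / 22.5."""
    insulin = np.asarray(insulin_mU_per_l, dtype=float)
    glucose = np.asarray(glucose_mmol_per_l, dtype=float)
    if np.any(insulin < 0) or np.any(glucose < 0):
        raise ValueError("insulin and glucose must be non-negative")
    out = insulin * glucose / 22.5
    return out.item() if out.ndim == 0 else out


def insulin_si_to_conventional(insulin_si):
    """Convert insulin from SI (pmol/l) to conventional units (mU/l) by /6."""
    x = np.asarray(insulin_si, dtype=float)
    if np.any(x < 0):
        raise ValueError("insulin must be non-negative")
    out = x / 6.0
    return out.item() if out.ndim == 0 else out


def crf(sex_code, age, bmi, heart_rate, srpa):
    """Non-exercise cardiorespiratory fitness estimate (ml/min/kg).

    CRF = sex*2.77 - age*0.1 - BMI*0.17 - heart_rate*0.04 + SRPA + 18.07,
    with sex coded 0 = female, 1 = male and SRPA a 1-5 self-reported
    physical-activity category.
    """
    sex_code = np.asarray(sex_code, dtype=float)
    srpa_arr = np.asarray(srpa, dtype=float)
    if np.any((sex_code != 0) & (sex_code != 1)):
        raise ValueError("sex_code must be 0 (female) or 1 (male)")
    if np.any((srpa_arr != 0) & ((srpa_arr < 1) | (srpa_arr > 5))):
        warnings.warn("SRPA outside the 1-5 questionnaire range", stacklevel=2)
    out = (
        sex_code * 2.77
        - np.asarray(age, float) * 0.1
        - np.asarray(bmi, float) * 0.17
        - np.asarray(heart_rate, float) * 0.04
        + srpa_arr
        + 18.07
    )
    return out.item() if out.ndim == 0 else out


def ms_score(waist_cm, height_cm, glucose_mmol, triglycerides_mmol,
             sbp_mmhg, hdl, sex_code, hdl_in_mmol: bool = True):
    """Continuous metabolic-syndrome severity score.

    MS = 2*waist/height + glucose/5.6 + triglycerides/1.7 + SBP/130
         - HDL/(40 if male else 50)

    The HDL denominators follow the mg/dl convention; by default HDL given
    in mmol/l is converted (x 38.67) before entering the score
    (``hdl_in_mmol=False`` takes HDL as mg/dl directly).
    """
    height = np.asarray(height_cm, dtype=float)
    hdl_arr = np.asarray(hdl, dtype=float)
    sex = np.asarray(sex_code, dtype=float)
    if np.any(height <= 0):
        raise ValueError("height must be positive")
    if np.any(hdl_arr <= 0):
        raise ValueError("HDL must be positive")
    if hdl_in_mmol:
        hdl_arr = hdl_arr * HDL_MMOL_TO_MG_DL
    denom = np.where(sex == 1, 40.0, 50.0)
    out = (
        2.0 * np.asarray(waist_cm, float) / height
        + np.asarray(glucose_mmol, float) / 5.6
        + np.asarray(triglycerides_mmol, float) / 1.7
        + np.asarray(sbp_mmhg, float) / 130.0
        - hdl_arr / denom
    )
    return out.item() if out.ndim == 0 else out


def classify_glycemia(glucose_mmol_per_l):
    """Classify fasting glucose into normoglycemia / prediabetes /
    excluded_diabetes_range.  Bounds 5.6 and 6.9 mmol/l are inclusive for
    pre-diabetes; above 6.9 falls in the (excluded) diabetes range."""
    g = np.asarray(glucose_mmol_per_l, dtype=float)
    if np.any(g <= 0):
        raise ValueError("glucose must be positive")
    labels = np.where(
        g < GLYCEMIA_LOWER_MMOL, "normoglycemia",
        np.where(g <= GLYCEMIA_UPPER_MMOL, "prediabetes",
                 "excluded_diabetes_range"),
    )
    return labels.item() if labels.ndim == 0 else labels


def al_ratio(adiponectin_ng_ml, leptin_ng_ml):
    """Adiponectin / leptin ratio (dimensionless; both ng/ml)."""
    lep = np.asarray(leptin_ng_ml, dtype=float)
    if np.any(lep <= 0):
        raise ValueError("leptin must be positive")
    out = np.asarray(adiponectin_ng_ml, dtype=float) / lep
    return out.item() if out.ndim == 0 else out


def round_half_up(x, decimals: int = 1):
    """Half-up rounding at report precision (one decimal, as in the tables)."""
    q = Decimal(1).scaleb(-decimals)

    def _one(v: float) -> float:
        return float(Decimal(repr(float(v))).quantize(q, rounding=ROUND_HALF_UP))

    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        return _one(float(arr))
    return np.vectorize(_one)(arr)


def add_derived_columns(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append HOMA, CRF, MS and A/L ratio columns derived from raw measures."""
    out = cohort.copy()
    out["homa"] = homa(out["insulin"].to_numpy(), out["glucose"].to_numpy())
    out["crf"] = crf(out["sex_code"].to_numpy(), out["age"].to_numpy(),
                     out["bmi"].to_numpy(), out["heart_rate"].to_numpy(),
                     out["srpa"].to_numpy())
    out["ms"] = ms_score(out["waist"].to_numpy(), out["height"].to_numpy(),
                         out["glucose"].to_numpy(),
                         out["triglycerides"].to_numpy(),
                         out["sbp"].to_numpy(), out["hdl"].to_numpy(),
                         out["sex_code"].to_numpy())
    out["al_ratio"] = al_ratio(out["adiponectin"].to_numpy(),
                               out["leptin"].to_numpy())
    return out
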