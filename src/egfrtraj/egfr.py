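"""Creatinine-to-eGFR conversion via the race-free CKD-EPI 2021 equation.

For serum creatinine Scr in mg/dL (µmol/L divided by 88.42), age in years and
sex (0 = female, 1 = male):

    eGFR = 142 * min(Scr/kappa, 1)^alpha * max(Scr/kappa, 1)^-1.200
               * 0.9938^age * (1.012 if female)

with kappa = 0.7 (female) / 0.9 (male) and alpha = -0.241 / -0.302.  The
result is in mL/min/1.73m^2; chronic kidney disease (CKD) is flagged at
eGFR < 60.  The closed-form piecewise inverse is also provided (used by the
synthetic-data generator to turn latent eGFR paths into creatinine).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "UMOL_PER_MGDL",
    "CKD_THRESHOLD",
    "ckd_epi_2021",
    "inverse_ckd_epi_2021",
    "compute_age_at_exam",
    "make_assessments",
]

UMOL_PER_MGDL = 88.42
CKD_THRESHOLD = 60.0

_KAPPA = np.array([0.7, 0.9])  # indexed by sex (0 female, 1 male)
_ALPHA = np.array([-0.241, -0.302])
_SEX_MULT = np.array([1.012, 1.0])
_AGE_BASE = 0.9938
_SCALE = 142.0
_EXP_HIGH = -1.200


def _as_arrays(creatinine_umol, age_years, sex):
    crea = np.asarray(creatinine_umol, dtype=float)
    age = np.asarray(age_years, dtype=float)
    sex = np.asarray(sex, dtype=int)
    if np.any(crea <= 0) or np.any(~np.isfinite(crea)):
        raise ValueError("creatinine must be positive and finite")
    if np.any(age <= 0) or np.any(~np.isfinite(age)):
        raise ValueError("age must be positive and finite")
    if np.any((sex != 0) & (sex != 1)):
        raise ValueError("sex must be coded 0 (female) or 1 (male)")
    return crea, age, sex


def ckd_epi_2021(creatinine_umol, age_years, sex):
    """Estimated GFR (mL/min/1.73m^2) from creatinine (µmol/L), age and sex.

    Vectorised over all arguments; scalars in give a scalar out.  Strictly
    decreasing in creatinine at fixed age/sex and in age at fixed
    creatinine/sex, and continuous at the knot Scr = kappa.
    """
    crea, age, sex = _as_arrays(creatinine_umol, age_years, sex)
    scalar = crea.ndim == 0 and age.ndim == 0 and np.asarray(sex).ndim == 0
    crea, age, sex = np.atleast_1d(crea), np.atleast_1d(age), np.atleast_1d(sex)
    ratio = crea / UMOL_PER_MGDL / _KAPPA[sex]
    egfr = (
        _SCALE
        * np.minimum(ratio, 1.0) ** _ALPHA[sex]
        * np.maximum(ratio, 1.0) ** _EXP_HIGH
        * _AGE_BASE**age
        * _SEX_MULT[sex]
    )
    return float(egfr[0]) if scalar else egfr


def inverse_ckd_epi_2021(egfr, age_years, sex):
    """Serum creatinine (µmol/L) producing a given eGFR at fixed age and sex.

    The equation is piecewise in the ratio r = Scr/kappa with a negative
    exponent on each branch, so it is globally invertible: with
    C = 142 * 0.9938^age * sex multiplier, eGFR >= C corresponds to the
    r <= 1 branch and eGFR < C to the r > 1 branch; each branch is solved in
    closed form and the branch consistent with its own domain is selected.
    """
    egfr_arr = np.asarray(egfr, dtype=float)
    age = np.asarray(age_years, dtype=float)
    sex = np.asarray(sex, dtype=int)
    if np.any(egfr_arr <= 0):
        raise ValueError("eGFR must be positive")
    scalar = egfr_arr.ndim == 0 and age.ndim == 0 and np.asarray(sex).ndim == 0
    egfr_arr, age, sex = np.atleast_1d(egfr_arr), np.atleast_1d(age), np.atleast_1d(sex)
    c = _SCALE * _AGE_BASE**age * _SEX_MULT[sex]
    g = egfr_arr / c
    ratio = np.where(g >= 1.0, g ** (1.0 / _ALPHA[sex]), g ** (1.0 / _EXP_HIGH))
    crea = ratio * _KAPPA[sex] * UMOL_PER_MGDL
    return float(crea[0]) if scalar else crea


def compute_age_at_exam(birth_year, birth_month, exam_date) -> np.ndarray | float:
    """Age in years (days / 365.25) at an exam date.

    Only birth year and month are available in biobank-style data; the day of
    birth is imputed as the 15th of the month.  Raises if any exam precedes
    the (imputed) birth date.
    """
    years = np.atleast_1d(np.asarray(birth_year, dtype=int))
    months = np.atleast_1d(np.asarray(birth_month, dtype=int))
    exams = pd.to_datetime(pd.Series(np.atleast_1d(exam_date)))
    birth = pd.to_datetime(
        pd.DataFrame({"year": years, "month": months, "day": 15})
    )
    days = (exams.to_numpy() - birth.to_numpy()).astype("timedelta64[D]").astype(float)
    if np.any(days < 0):
        raise ValueError("exam date precedes birth date")
    age = days / 365.25
    return float(age[0]) if np.isscalar(exam_date) or isinstance(exam_date, (str, pd.Timestamp)) else age


def make_assessments(
    records: pd.DataFrame,
    covariates: pd.DataFrame,
    value_col: str = "value",
) -> pd.DataFrame:
    """Turn creatinine records into dated eGFR assessments.

    ``value_col`` selects the creatinine column (``value`` for SC records,
    ``value_corrected`` for bias-corrected eMR records).  Persons missing from
    the covariate table (no sex or birth date) are dropped, since eGFR cannot
    be computed for them.
    """
    needed = covariates[["person_id", "sex", "birth_year", "birth_month"]].dropna()
    df = records.merge(needed, on="person_id", how="inner").copy()
    if df.empty:
        return pd.DataFrame(
            columns=["person_id", "exam_date", "source", "creatinine", "age_at_exam",
                     "sex", "egfr", "ckd", "bias_corrected"]
        )
    age = compute_age_at_exam(
        df["birth_year"].to_numpy(int), df["birth_month"].to_numpy(int), df["exam_date"]
    )
    sex = df["sex"].to_numpy(int)
    crea = df[value_col].to_numpy(float)
    egfr = ckd_epi_2021(crea, age, sex)
    out = pd.DataFrame(
        {
            "person_id": df["person_id"].to_numpy(),
            "exam_date": df["exam_date"].to_numpy(),
            "source": df["source"].to_numpy(),
            "creatinine": crea,
            "age_at_exam": np.asarray(age, dtype=float),
            "sex": sex,
            "egfr": np.asarray(egfr, dtype=float),
        }
    )
    out["ckd"] = out["egfr"] < CKD_THRESHOLD
    out["bias_corrected"] = value_col != "value"
    return out
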