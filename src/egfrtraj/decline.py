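"""Annualized eGFR decline: per-person estimates, cohort mean, regressions.

A person's annual decline is the first-to-last annualized difference on the
censored trajectory,

    decline = (eGFR_first - eGFR_last) / years between,

so a positive value means kidney function is falling.  Eligibility requires
at least two remaining assessments with first and last dates at least 365
days apart.  Cohort-level inference is the arithmetic mean with a normal
approximation CI (mean +/- 1.96 SE); risk-factor associations are ordinary
least squares of the per-person decline on covariates.  Around acute kidney
injury (AKI), decline is computed between the assessment at least six months
before the incident event that is closest to six months, and likewise after.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "annual_decline",
    "mean_decline_ci",
    "decline_regression",
    "aki_peri_decline",
    "REGRESSION_MODELS",
]

MIN_SPAN_DAYS = 365
PERI_AKI_MIN_DAYS = 183

#: Covariate sets of the two standard regression models.  Age is the age at
#: first assessment centered at 40 years; obesity is BMI >= 30 kg/m^2.
REGRESSION_MODELS = {
    "genetic": ("age_centered", "sex", "variant_dosage"),
    "lifestyle": ("age_centered", "sex", "smoking", "obesity", "diabetes"),
}


def annual_decline(assessments: pd.DataFrame) -> pd.DataFrame:
    """Per-person annualized eGFR decline from censored trajectories.

    Uses only the first and last assessment of each person (intermediate
    assessments affect neither the estimate nor eligibility beyond counting).
    Returns one row per person with ``eligible``, a ``reason`` code for
    ineligible persons (``single_assessment`` or ``span_lt_1yr``), the
    decline, the span in years, the endpoint eGFR values, and the age and
    date at first assessment (used by the regressions).
    """
    if assessments.empty:
        return pd.DataFrame(
            columns=["person_id", "eligible", "reason", "decline", "years_between",
                     "n_assessments", "egfr_first", "egfr_last", "first_date", "age_first"]
        )
    srt = assessments.sort_values(["person_id", "exam_date"], kind="stable")
    grp = srt.groupby("person_id")
    first = grp.first()
    last = grp.last()
    n = grp.size()
    days = (last["exam_date"] - first["exam_date"]).dt.days
    years = days / 365.25
    eligible = (n >= 2) & (days >= MIN_SPAN_DAYS)
    decline = (first["egfr"] - last["egfr"]) / years
    out = pd.DataFrame(
        {
            "person_id": first.index,
            "eligible": eligible.to_numpy(),
            "reason": np.where(n < 2, "single_assessment",
                               np.where(days < MIN_SPAN_DAYS, "span_lt_1yr", "")),
            "decline": np.where(eligible, decline, np.nan),
            "years_between": years.to_numpy(),
            "n_assessments": n.to_numpy(),
            "egfr_first": first["egfr"].to_numpy(),
            "egfr_last": last["egfr"].to_numpy(),
            "first_date": first["exam_date"].to_numpy(),
            "age_first": first["age_at_exam"].to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def mean_decline_ci(declines) -> tuple[float, float, float]:
    """Arithmetic mean of per-person declines with a 95% normal CI.

    CI = mean +/- 1.96 * SD / sqrt(n).  Requires at least two values.
    """
    x = np.asarray(pd.Series(declines).dropna(), dtype=float)
    if x.size < 2:
        raise ValueError(f"need at least 2 per-person declines, got {x.size}")
    mean = float(x.mean())
    se = float(x.std(ddof=1) / np.sqrt(x.size))
    return mean, mean - 1.96 * se, mean + 1.96 * se


def _build_design(merged: pd.DataFrame, model: str) -> pd.DataFrame:
    if model not in REGRESSION_MODELS:
        raise ValueError(f"unknown model '{model}'; choose from {sorted(REGRESSION_MODELS)}")
    design = pd.DataFrame(index=merged.index)
    design["age_centered"] = merged["age_first"] - 40.0
    design["sex"] = merged["sex"]
    if model == "genetic":
        design["variant_dosage"] = merged["variant_dosage"]
    else:
        design["smoking"] = merged["smoking"]
        design["obesity"] = (merged["bmi"] >= 30.0).where(merged["bmi"].notna()).astype(float)
        design["diabetes"] = merged["diabetes"]
    return design[list(REGRESSION_MODELS[model])]


def decline_regression(
    person_table: pd.DataFrame, covariates: pd.DataFrame, model: str = "genetic"
) -> pd.DataFrame:
    """OLS of per-person annual decline on a standard covariate set.

    ``model='genetic'`` regresses on age (centered at 40), sex and the
    variant allele dosage; ``model='lifestyle'`` on age, sex, smoking,
    obesity (BMI >= 30) and diabetes.  Persons with any missing covariate are
    dropped listwise.  Returns a coefficient table with ``term, beta, se,
    ci_low, ci_high, n_persons, m_assessments`` (CI = beta +/- 1.96 SE).

    Raises on a rank-deficient or zero-variance design, naming the offending
    columns, rather than silently dropping terms.
    """
    eligible = person_table[person_table["eligible"]].copy()
    merged = eligible.merge(covariates, on="person_id", how="left")
    design = _build_design(merged, model)
    complete = design.notna().all(axis=1) & merged["decline"].notna()
    design, merged = design[complete], merged[complete]
    if len(design) <= design.shape[1] + 1:
        raise ValueError(f"too few complete cases ({len(design)}) for model '{model}'")

    constant = [c for c in design.columns if design[c].nunique() <= 1]
    if constant:
        raise ValueError(f"zero-variance covariate column(s): {constant}")
    x = sm.add_constant(design.astype(float), prepend=True)
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        corr = design.astype(float).corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        collinear = sorted(set(corr.index[(corr > 0.999999).any(axis=1)]))
        raise ValueError(f"rank-deficient design; collinear column(s): {collinear}")

    fit = sm.OLS(merged["decline"].astype(float), x).fit()
    table = pd.DataFrame(
        {
            "term": ["intercept", *design.columns],
            "beta": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
        }
    )
    table["ci_low"] = table["beta"] - 1.96 * table["se"]
    table["ci_high"] = table["beta"] + 1.96 * table["se"]
    table["n_persons"] = len(design)
    table["m_assessments"] = int(merged["n_assessments"].sum())
    return table


def aki_peri_decline(
    assessments: pd.DataFrame, events: pd.DataFrame
) -> tuple[float, float, float, int, pd.DataFrame]:
    """Mean annualized eGFR decline across incident AKI events.

    Incident AKI is a person's first AKI record dated strictly after their
    first assessment.  For each such person the pre-AKI assessment is the one
    at least 183 days before the event minimizing the gap to 183 days (i.e.
    the latest qualifying one), and symmetrically after; persons lacking a
    qualifying assessment on either side are excluded.  The per-person
    decline (before - after, annualized over the actual span) is aggregated
    as in :func:`mean_decline_ci`.

    Returns ``(mean, ci_low, ci_high, n_persons, per_person_table)``.
    """
    empty = pd.DataFrame(columns=["person_id", "aki_date", "decline"])
    aki = events[events["category"] == "AKI"]
    if aki.empty or assessments.empty:
        return np.nan, np.nan, np.nan, 0, empty
    first_exam = assessments.groupby("person_id")["exam_date"].min()
    aki = aki.merge(first_exam.rename("first_exam"), on="person_id", how="inner")
    aki = aki[aki["event_date"] > aki["first_exam"]]
    incident = aki.groupby("person_id")["event_date"].min().rename("aki_date")

    a = assessments.merge(incident, on="person_id", how="inner")
    a["offset_days"] = (a["exam_date"] - a["aki_date"]).dt.days

    before = a[a["offset_days"] <= -PERI_AKI_MIN_DAYS]
    before = before.sort_values(["person_id", "exam_date"]).groupby("person_id").last()
    after = a[a["offset_days"] >= PERI_AKI_MIN_DAYS]
    after = after.sort_values(["person_id", "exam_date"]).groupby("person_id").first()

    both = before.join(after, lsuffix="_before", rsuffix="_after", how="inner")
    if both.empty:
        return np.nan, np.nan, np.nan, 0, empty
    years = (both["exam_date_after"] - both["exam_date_before"]).dt.days / 365.25
    per_person = pd.DataFrame(
        {
            "person_id": both.index,
            "aki_date": both["aki_date_before"].to_numpy(),
            "egfr_before": both["egfr_before"].to_numpy(),
            "egfr_after": both["egfr_after"].to_numpy(),
            "years_between": years.to_numpy(),
            "decline": ((both["egfr_before"] - both["egfr_after"]) / years).to_numpy(),
        }
    ).reset_index(drop=True)
    if len(per_person) < 2:
        return float(per_person["decline"].mean()), np.nan, np.nan, len(per_person), per_person
    mean, lo, hi = mean_decline_ci(per_person["decline"])
    return mean, lo, hi, len(per_person), per_person
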