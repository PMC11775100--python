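"""Trajectory assembly: merging assessments, event censoring and summaries.

SC- and (bias-corrected) eMR-based eGFR assessments are merged per person by
date; same-date assessments from the two sources are both kept, as distinct
measurements.  Diagnostic events are attached by person, and censoring rules
prepare trajectories for decline estimation:

* assessments strictly after the earliest kidney-relevant event (AKI, ESKD,
  dialysis, transplant or nephrectomy) are removed;
* once an assessment shows eGFR < 15 mL/min/1.73m^2, that assessment is kept
  (it defines onset) but all later ones are removed;
* assessments within +/-183 days of any pregnancy event are removed (kidney
  physiology during pregnancy does not reflect chronic function);
* diabetes events annotate but never censor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .records_io import EMR, KIDNEY_CENSOR_CATEGORIES

__all__ = [
    "merge_by_person_date",
    "eligibility_flags",
    "censor_for_decline",
    "descriptive_summary",
    "event_split_summary",
    "plot_trajectory",
]

PREGNANCY_WINDOW_DAYS = 183
EGFR_CENSOR_THRESHOLD = 15.0


def merge_by_person_date(
    sc_assessments: pd.DataFrame, emr_assessments: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge SC and eMR eGFR assessments into per-person trajectories.

    Keeps at most one assessment per (person, date, source) and orders each
    person's assessments chronologically (SC before eMR on shared dates, for
    a deterministic order).  Returns the merged assessment table and the
    per-person eligibility flags from :func:`eligibility_flags`.
    """
    merged = pd.concat([sc_assessments, emr_assessments], ignore_index=True)
    merged = merged.drop_duplicates(subset=["person_id", "exam_date", "source"], keep="first")
    merged = merged.sort_values(
        ["person_id", "exam_date", "source"], kind="stable"
    ).reset_index(drop=True)
    return merged, eligibility_flags(merged)


def eligibility_flags(assessments: pd.DataFrame) -> pd.DataFrame:
    """Per-person assessment counts and trajectory eligibility flags.

    Flags: at least two assessments; at least two spanning one year or more;
    at least ten; and GP-clinical membership (any eMR-sourced assessment).
    """
    if assessments.empty:
        return pd.DataFrame(
            columns=["person_id", "n_assessments", "has_two", "has_two_one_year_apart",
                     "has_ten", "gp_member"]
        )
    grp = assessments.groupby("person_id")
    flags = grp.agg(
        n_assessments=("exam_date", "size"),
        first_date=("exam_date", "min"),
        last_date=("exam_date", "max"),
    )
    flags["has_two"] = flags["n_assessments"] >= 2
    flags["has_two_one_year_apart"] = flags["has_two"] & (
        (flags["last_date"] - flags["first_date"]).dt.days >= 365
    )
    flags["has_ten"] = flags["n_assessments"] >= 10
    flags["gp_member"] = grp["source"].agg(lambda s: (s == EMR).any())
    return flags.drop(columns=["first_date", "last_date"]).reset_index()


def censor_for_decline(assessments: pd.DataFrame, events: pd.DataFrame) -> pd.DataFrame:
    """Apply event- and value-based censoring ahead of decline estimation.

    The returned assessments are always a subsequence of the input for each
    person; censoring never adds or reorders rows.
    """
    a = assessments.sort_values(["person_id", "exam_date", "source"], kind="stable")
    a = a.reset_index(drop=True)
    keep = pd.Series(True, index=a.index)

    if events is not None and not events.empty:
        kidney = events[events["category"].isin(KIDNEY_CENSOR_CATEGORIES)]
        if not kidney.empty:
            first_event = kidney.groupby("person_id")["event_date"].min()
            cutoff = a["person_id"].map(first_event)
            keep &= cutoff.isna() | (a["exam_date"] <= cutoff)

        pregnancy = events[events["category"] == "pregnancy"]
        if not pregnancy.empty:
            joined = a[["person_id", "exam_date"]].reset_index().merge(
                pregnancy[["person_id", "event_date"]], on="person_id", how="inner"
            )
            near = (
                (joined["exam_date"] - joined["event_date"]).dt.days.abs()
                <= PREGNANCY_WINDOW_DAYS
            )
            keep[joined.loc[near, "index"].unique()] = False

    # eGFR < 15: keep the triggering assessment, drop strictly later ones.
    low = a[keep & (a["egfr"] < EGFR_CENSOR_THRESHOLD)]
    if not low.empty:
        first_low = low.groupby("person_id")["exam_date"].min()
        cutoff = a["person_id"].map(first_low)
        keep &= cutoff.isna() | (a["exam_date"] <= cutoff)

    return a[keep].reset_index(drop=True)


def _stratum_stats(
    persons: pd.Series,
    assessments: pd.DataFrame,
    covariates: pd.DataFrame,
    label: str,
) -> dict:
    """Descriptive statistics for one stratum of persons."""
    sub = assessments[assessments["person_id"].isin(persons)]
    cov = covariates[covariates["person_id"].isin(persons)]
    n = int(persons.size)
    row = {"stratum": label, "n_persons": n, "n_assessments": int(len(sub))}
    if n == 0 or sub.empty:
        return row
    grp = sub.sort_values(["person_id", "exam_date"]).groupby("person_id")
    first = grp.first()
    last = grp.last()
    sc_rows = sub[sub["source"] == "SC"]
    sc_baseline = (
        sc_rows.sort_values(["person_id", "exam_date"]).groupby("person_id")["egfr"].first()
        if not sc_rows.empty
        else pd.Series(dtype=float)
    )
    span_years = (last["exam_date"] - first["exam_date"]).dt.days / 365.25
    counts = grp.size()
    row.update(
        age_first_mean=float(first["age_at_exam"].mean()),
        age_first_sd=float(first["age_at_exam"].std()),
        pct_female=float((cov["sex"] == 0).mean() * 100) if len(cov) else np.nan,
        pct_smoking=float(cov["smoking"].mean() * 100) if cov["smoking"].notna().any() else np.nan,
        bmi_mean=float(cov["bmi"].mean()) if cov["bmi"].notna().any() else np.nan,
        pct_diabetes=float(cov["diabetes"].mean() * 100) if cov["diabetes"].notna().any() else np.nan,
        egfr_first_mean=float(first["egfr"].mean()),
        egfr_last_mean=float(last["egfr"].mean()),
        egfr_sc_baseline_mean=float(sc_baseline.mean()) if len(sc_baseline) else np.nan,
        pct_ckd_ever=float(grp["ckd"].any().mean() * 100),
        span_years_median=float(span_years.median()),
        span_years_max=float(span_years.max()),
        assessments_median=float(counts.median()),
        assessments_q1=float(counts.quantile(0.25)),
        assessments_q3=float(counts.quantile(0.75)),
    )
    return row


def descriptive_summary(
    assessments: pd.DataFrame,
    flags: pd.DataFrame,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Cohort descriptives per stratum.

    Strata: all persons; those with >=2 assessments; >=10 assessments;
    GP-clinical members and non-members.  Strata are nested (>=10 within >=2
    within all) so person counts are monotone.  Empty strata report n = 0
    with missing statistics.
    """
    strata = {
        "all": flags["person_id"],
        ">=2_assessments": flags.loc[flags["has_two"], "person_id"],
        ">=10_assessments": flags.loc[flags["has_ten"], "person_id"],
        "gp_member": flags.loc[flags["gp_member"], "person_id"],
        "not_gp_member": flags.loc[~flags["gp_member"].astype(bool), "person_id"],
    }
    rows = [
        _stratum_stats(persons, assessments, covariates, label)
        for label, persons in strata.items()
    ]
    return pd.DataFrame(rows)


def event_split_summary(assessments: pd.DataFrame, events: pd.DataFrame) -> pd.DataFrame:
    """Count persons with any event per category, split at the first assessment.

    For each category, a person is counted under ``before`` if they have any
    such event dated on or before their first assessment and under ``after``
    if any is dated strictly after; the two columns partition each person's
    events relative to their first assessment date.
    """
    if assessments.empty or events is None or events.empty:
        return pd.DataFrame(columns=["category", "n_persons_before", "n_persons_after"])
    first = assessments.groupby("person_id")["exam_date"].min().rename("first_exam")
    ev = events.merge(first, on="person_id", how="inner")
    ev["after"] = ev["event_date"] > ev["first_exam"]
    rows = []
    for category, grp in ev.groupby("category"):
        rows.append(
            {
                "category": category,
                "n_persons_before": int(grp.loc[~grp["after"], "person_id"].nunique()),
                "n_persons_after": int(grp.loc[grp["after"], "person_id"].nunique()),
            }
        )
    return pd.DataFrame(rows)


def plot_trajectory(person_assessments: pd.DataFrame, person_events: pd.DataFrame | None = None, ax=None):
    """Simple date-vs-eGFR plot for one person, with the CKD band and events.

    Requires matplotlib (optional dependency); returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    sub = person_assessments.sort_values("exam_date")
    for source, marker, color in ((EMR, "o", "tab:red"), ("SC", "s", "black")):
        part = sub[sub["source"] == source]
        if not part.empty:
            ax.plot(part["exam_date"], part["egfr"], marker, color=color, label=source)
    ax.axhspan(0, 60, alpha=0.12, color="grey", label="CKD (eGFR < 60)")
    if person_events is not None:
        for ev in person_events.itertuples():
            ax.axvline(ev.event_date, linestyle=":", alpha=0.7)
            ax.annotate(ev.category, (ev.event_date, ax.get_ylim()[1]), fontsize=8)
    ax.set_xlabel("date")
    ax.set_ylabel("eGFR (mL/min/1.73m$^2$)")
    ax.legend(loc="best", fontsize=8)
    return ax
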