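"""Per-calendar-year multiplicative bias estimation and correction.

Routine-care (eMR) creatinine measured before assay standardization is
systematically shifted relative to gold-standard study-center (SC) values.
Writing X = ln(crea_SC) ~ N(mu, sigma^2) and X* = ln(crea_eMR) ~
N(mu*, sigma*^2), the model assumes an additive log-scale error

    X* = X + s + E_r*,   E_r* ~ N(0, sigma*^2),

so the systematic component per calendar year is s = mu* - mu, estimated on
persons with both measurements in the same calendar year (pairing each SC
draw with the eMR value closest in time).  On the original scale exp(s) is
the ratio of geometric means.  We report the correction factor in the
SC-over-eMR direction,

    factor_year = GM(SC) / GM(eMR) = exp(-s_year),

so that corrected eMR = eMR * factor_year, i.e. ln-scale subtraction of the
estimated bias.  Factors below one therefore mean eMR ran high that year.

Years without paired data receive proxy factors: interior gaps are
interpolated linearly on the log scale between the flanking estimated years;
years before the first estimated year carry its factor; years after the last
estimated year get factor 1.0 (no correction) when the last estimate is
already close to unity, otherwise they carry it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BiasOptions",
    "Provenance",
    "pair_same_year",
    "estimate_year_bias",
    "build_bias_table",
    "apply_bias_correction",
]


class Provenance:
    """How a bias-table entry was obtained."""

    ESTIMATED = "estimated"
    ESTIMATED_WINSORIZED = "estimated_winsorized"
    INTERPOLATED = "interpolated"
    BOUNDARY_CARRY = "boundary_carry"
    UNITY = "unity"


@dataclass(frozen=True)
class BiasOptions:
    """Tunable settings of the bias model.

    ``min_pairs`` is the minimum number of same-year SC/eMR pairs required to
    estimate a year directly (years below it fall back to proxy rules).
    ``unity_threshold`` gates the post-last-year rule: when the last estimated
    factor is within this distance of 1, later years get no correction.
    ``winsor_z`` is the log-scale z-cutoff used when winsorizing.
    """

    min_pairs: int = 100
    winsorize: bool = False
    winsor_z: float = 3.0
    unity_threshold: float = 0.05


def pair_same_year(
    sc_records: pd.DataFrame, emr_records: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair each SC draw with the same-calendar-year eMR value closest in time.

    At most one pair per person per SC visit; ties in closeness are broken by
    the earlier eMR date.  Persons lacking a same-year eMR value are omitted.

    Returns
    -------
    (pairs, year_stats)
        ``pairs`` has columns ``person_id, year, sc_date, emr_date, sc_value,
        emr_value``; ``year_stats`` reports per-year pair counts and the
        Spearman correlation between paired SC and eMR values.
    """
    sc = sc_records[["person_id", "exam_date", "value"]].rename(
        columns={"exam_date": "sc_date", "value": "sc_value"}
    )
    emr = emr_records[["person_id", "exam_date", "value"]].rename(
        columns={"exam_date": "emr_date", "value": "emr_value"}
    )
    sc = sc.assign(year=sc["sc_date"].dt.year)
    emr = emr.assign(year=emr["emr_date"].dt.year)
    merged = sc.merge(emr, on=["person_id", "year"], how="inner")
    if merged.empty:
        pairs = pd.DataFrame(
            columns=["person_id", "year", "sc_date", "emr_date", "sc_value", "emr_value"]
        )
        stats_df = pd.DataFrame(columns=["year", "n_pairs", "spearman"])
        return pairs, stats_df
    merged["gap_days"] = (merged["emr_date"] - merged["sc_date"]).dt.days.abs()
    merged = merged.sort_values(
        ["person_id", "sc_date", "gap_days", "emr_date"], kind="stable"
    )
    pairs = merged.groupby(["person_id", "sc_date"], as_index=False, sort=False).first()
    pairs = pairs[["person_id", "year", "sc_date", "emr_date", "sc_value", "emr_value"]]
    pairs = pairs.sort_values(["year", "person_id", "sc_date"]).reset_index(drop=True)

    rows = []
    for year, grp in pairs.groupby("year"):
        rho = np.nan
        if len(grp) >= 3 and grp["sc_value"].nunique() > 1 and grp["emr_value"].nunique() > 1:
            rho = float(stats.spearmanr(grp["sc_value"], grp["emr_value"]).statistic)
        rows.append({"year": int(year), "n_pairs": len(grp), "spearman": rho})
    return pairs, pd.DataFrame(rows)


def _winsorize_log(x: np.ndarray, z: float) -> np.ndarray:
    mean, sd = x.mean(), x.std(ddof=1) if x.size > 1 else 0.0
    return np.clip(x, mean - z * sd, mean + z * sd)


def estimate_year_bias(
    pairs: pd.DataFrame,
    winsorize: bool = False,
    min_pairs: int = 100,
    winsor_z: float = 3.0,
) -> pd.DataFrame:
    """Estimate the multiplicative bias factor per calendar year.

    For each year with at least ``min_pairs`` pairs the factor is the ratio of
    geometric means, GM(SC)/GM(eMR), computed on that year's paired sample.
    With ``winsorize=True``, ln(SC) and ln(eMR) are each first clamped to
    their own within-year mean +/- ``winsor_z`` SD, a robustness variant that
    limits the influence of extreme values.

    Returns a frame with columns ``year, factor, log_bias, n_pairs,
    provenance`` where ``log_bias`` is s = mean ln(eMR) - mean ln(SC) and
    ``factor = exp(-log_bias)``.
    """
    rows = []
    provenance = Provenance.ESTIMATED_WINSORIZED if winsorize else Provenance.ESTIMATED
    for year, grp in pairs.groupby("year"):
        if len(grp) < min_pairs:
            continue
        ln_sc = np.log(grp["sc_value"].to_numpy(float))
        ln_emr = np.log(grp["emr_value"].to_numpy(float))
        if winsorize:
            ln_sc = _winsorize_log(ln_sc, winsor_z)
            ln_emr = _winsorize_log(ln_emr, winsor_z)
        s = float(ln_emr.mean() - ln_sc.mean())
        rows.append(
            {
                "year": int(year),
                "factor": float(np.exp(-s)),
                "log_bias": s,
                "n_pairs": len(grp),
                "provenance": provenance,
            }
        )
    return pd.DataFrame(rows, columns=["year", "factor", "log_bias", "n_pairs", "provenance"])


def build_bias_table(
    estimates: pd.DataFrame,
    year_span: tuple[int, int] | None = None,
    unity_threshold: float = 0.05,
) -> pd.DataFrame:
    """Complete the per-year bias table over a span of calendar years.

    Rules for years without a direct estimate:

    * interior gaps: log-linear interpolation between the flanking estimated
      years (a single-year gap is the exponential of the mean of the two
      adjacent log biases);
    * years before the first estimated year: carry the first factor;
    * years after the last estimated year: factor 1.0 (no correction) when the
      last estimated factor is within ``unity_threshold`` of 1, otherwise
      carry the last factor.

    Factors are kept at full precision; round only for display.
    """
    if estimates is None or len(estimates) == 0:
        raise ValueError("cannot build a bias table from zero estimated years")
    est = estimates.sort_values("year").reset_index(drop=True)
    est_years = est["year"].to_numpy(int)
    log_factor = np.log(est["factor"].to_numpy(float))

    lo, hi = int(est_years.min()), int(est_years.max())
    if year_span is not None:
        lo, hi = min(lo, int(year_span[0])), max(hi, int(year_span[1]))

    by_year = {int(r.year): r for r in est.itertuples()}
    last_factor = float(est["factor"].iloc[-1])
    tail_is_unity = abs(last_factor - 1.0) <= unity_threshold

    rows = []
    for year in range(lo, hi + 1):
        if year in by_year:
            r = by_year[year]
            rows.append(
                {"year": year, "factor": float(r.factor), "log_bias": float(r.log_bias),
                 "provenance": r.provenance, "n_pairs": int(r.n_pairs)}
            )
        elif year < est_years[0]:
            rows.append(
                {"year": year, "factor": float(np.exp(log_factor[0])),
                 "log_bias": -float(log_factor[0]),
                 "provenance": Provenance.BOUNDARY_CARRY, "n_pairs": 0}
            )
        elif year > est_years[-1]:
            factor = 1.0 if tail_is_unity else last_factor
            prov = Provenance.UNITY if tail_is_unity else Provenance.BOUNDARY_CARRY
            rows.append(
                {"year": year, "factor": factor, "log_bias": -float(np.log(factor)),
                 "provenance": prov, "n_pairs": 0}
            )
        else:
            lf = float(np.interp(year, est_years, log_factor))
            rows.append(
                {"year": year, "factor": float(np.exp(lf)), "log_bias": -lf,
                 "provenance": Provenance.INTERPOLATED, "n_pairs": 0}
            )
    return pd.DataFrame(rows, columns=["year", "factor", "log_bias", "provenance", "n_pairs"])


def apply_bias_correction(
    emr_records: pd.DataFrame, bias_table: pd.DataFrame
) -> pd.DataFrame:
    """Apply per-year correction factors to eMR creatinine records.

    Each record's corrected value is ``value * factor[year]`` (subtraction of
    the estimated log bias).  The factor and its provenance are recorded per
    record.  Raises if any record's calendar year is not covered by the table.
    """
    factors = bias_table.set_index("year")["factor"]
    provenance = bias_table.set_index("year")["provenance"]
    years = emr_records["exam_date"].dt.year
    missing = sorted(set(years.unique()) - set(factors.index))
    if missing:
        raise ValueError(f"bias table does not cover calendar year(s): {missing}")
    out = emr_records.copy()
    out["correction_factor"] = years.map(factors).astype(float)
    out["bias_provenance"] = years.map(provenance)
    out["value_corrected"] = out["value"] * out["correction_factor"]
    return out
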