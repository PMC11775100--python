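"""Biobank-shaped synthetic cohorts with known ground truth.

The generator emulates the structure of combined study-center (SC) and
primary-care EHR (eMR) creatinine data: lognormal serum creatinine; SC visits
concentrated in a short baseline window (2007-2010) with a small follow-up
subset (2012-2013); eMR measurements spread over decades with visit frequency
increasing as latent kidney function falls; a calendar-year multiplicative
assay bias acting on eMR values before ~2013; sparse kidney-relevant
diagnostic events; and a small admixture of deliberately corrupt rows for QC
testing.

Each person carries a latent linear eGFR path

    eGFR(t) = eGFR_0 - slope * t          (t in years since SC baseline),

optionally interrupted by an acute-kidney-injury episode (abrupt drop with
partial recovery).  Creatinine at a visit is the closed-form piecewise
inverse of the CKD-EPI 2021 equation at the person's age and sex, and the
observed eMR value divides out the year's true bias factor and adds
lognormal measurement noise:

    eMR_observed = crea_true / factor(year) * exp(eps),  eps ~ N(0, noise_sd^2).

SC values carry the same noise but no bias.  Per-person true slopes are the
configured mean slope plus mean-centered covariate contributions plus person
noise, so the configured mean slope is the cohort-average decline by
construction and covariate effects are recoverable by regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .egfr import inverse_ckd_epi_2021, ckd_epi_2021
from .records_io import DEFAULT_CODELIST, EMR, SC, QcStatus

__all__ = [
    "DEFAULT_TRUE_BIAS",
    "SyntheticConfig",
    "SyntheticCohort",
    "SyntheticData",
    "true_bias_factor",
    "generate_cohort",
    "generate_measurements",
    "generate_dataset",
    "write_dataset",
]

#: True per-year bias schedule: the 2007-2013 factor ramp with the
#: interpolated 2011 value; years before 2007 use the 2007 factor and years
#: after 2013 are unbiased.
DEFAULT_TRUE_BIAS: dict[int, float] = {
    2007: 0.84,
    2008: 0.84,
    2009: 0.90,
    2010: 0.91,
    2011: 0.93,
    2012: 0.95,
    2013: 0.97,
}


def true_bias_factor(year: int | np.ndarray, schedule: Mapping[int, float]) -> np.ndarray:
    """Look up the true bias factor, extending the schedule to all years."""
    years = sorted(schedule)
    lo, hi = years[0], years[-1]
    y = np.atleast_1d(np.asarray(year, dtype=int))
    out = np.ones(y.shape, dtype=float)
    out[y < lo] = schedule[lo]
    for yr in years:
        out[y == yr] = schedule[yr]
    return out if np.ndim(year) else float(out[0])


@dataclass
class SyntheticConfig:
    """All knobs of the generator; the seed fully determines the output.

    Defaults describe a 2,000-person cohort observed 1990-2017 with a true
    mean decline of 1.0 mL/min/1.73m^2 per year and covariate effects on the
    slope (per year of age above 40, male sex, smoking, diabetes, per variant
    allele) matching the magnitudes typical of biobank-scale decline
    regressions.  ``noise_sd`` is the SD of the lognormal measurement error
    on the log scale; ``ln_crea_mean`` gives the baseline log-creatinine
    location (µmol/L) per sex.
    """

    n_persons: int = 2000
    seed: int = 7

    # calendar structure; each person's first SC visit falls uniformly in
    # sc_visit_years, and a small follow-up subset gets a second SC visit in
    # a strictly later year of the same set
    year_start: int = 1990
    year_end: int = 2017
    sc_visit_years: tuple[int, ...] = (2007, 2008, 2009, 2010, 2012, 2013)
    followup_fraction: float = 0.04
    emr_start_min: int = 1990
    emr_start_max: int = 2013

    # measurement model
    bias_schedule: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_TRUE_BIAS))
    noise_sd: float = 0.05
    ln_crea_mean: tuple[float, float] = (math.log(62.0), math.log(76.0))  # (female, male)
    ln_crea_sd: float = 0.15

    # decline model (slope units: mL/min/1.73m^2 per year); slope_sd is set
    # so the realized SD of per-person two-point annualized declines is ~2.2,
    # the dispersion implied by biobank-scale decline CIs and regression SEs
    mean_slope: float = 1.0
    slope_sd: float = 2.1
    age_effect: float = 0.005
    male_effect: float = 0.10
    smoking_effect: float = 0.026
    obesity_effect: float = 0.0
    diabetes_effect: float = 0.383
    variant_effect: float = 0.052

    # covariate marginals
    male_fraction: float = 0.458
    age_min: float = 40.0
    age_max: float = 70.0
    smoking_prevalence: float = 0.45
    diabetes_prevalence: float = 0.05
    bmi_mean: float = 27.4
    bmi_sd: float = 4.8
    allele_freq: float = 0.2

    # visit-intensity model: expected eMR measurements per year, rising as
    # latent eGFR falls below a healthy reference level
    visit_base_rate: float = 0.5
    visit_egfr_coef: float = 0.03
    visit_rate_cap: float = 12.0
    visit_intensity_active: bool = True

    # diagnostic-event hazards (per person-year over the eMR window)
    aki_hazard: float = 0.004
    eskd_hazard: float = 0.0005
    dialysis_hazard: float = 0.0003
    transplant_hazard: float = 0.0003
    nephrectomy_hazard: float = 0.0015
    pregnancy_hazard: float = 0.03
    pregnancy_age_max: float = 45.0
    diabetes_code_prob: float = 0.8

    # AKI episode shape
    aki_drop: float = 20.0
    aki_recovery_frac: float = 0.7
    aki_recovery_years: float = 1.0
    egfr_floor: float = 3.0

    # corrupt-row injection rates (fractions of clean eMR rows)
    corrupt_duplicate_rate: float = 0.01
    corrupt_above_max_rate: float = 0.002
    corrupt_below_lod_rate: float = 0.002

    def validate(self) -> None:
        if self.n_persons <= 0:
            raise ValueError("n_persons must be positive")
        if self.noise_sd < 0 or self.slope_sd < 0 or self.ln_crea_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if any(f <= 0 for f in self.bias_schedule.values()):
            raise ValueError("bias factors must be positive")
        hazards = (self.aki_hazard, self.eskd_hazard, self.dialysis_hazard,
                   self.transplant_hazard, self.nephrectomy_hazard,
                   self.pregnancy_hazard, self.visit_base_rate)
        if any(h < 0 for h in hazards):
            raise ValueError("rates and hazards must be non-negative")
        if not self.year_start <= min(self.sc_visit_years) <= self.year_end:
            raise ValueError("SC visit years must lie inside the year span")


@dataclass
class SyntheticCohort:
    covariates: pd.DataFrame
    truth: pd.DataFrame


@dataclass
class SyntheticData:
    covariates: pd.DataFrame
    truth: pd.DataFrame
    sc: pd.DataFrame
    emr: pd.DataFrame
    events: pd.DataFrame


_CATEGORY_CODES = {}
for _code, _cat in DEFAULT_CODELIST.items():
    _CATEGORY_CODES.setdefault(_cat, _code)


def _rngs(config: SyntheticConfig) -> tuple[np.random.Generator, np.random.Generator]:
    children = np.random.SeedSequence(config.seed).spawn(2)
    return np.random.default_rng(children[0]), np.random.default_rng(children[1])


def _random_dates_in_year(years: np.ndarray, rng: np.random.Generator) -> pd.DatetimeIndex:
    start = pd.to_datetime(pd.DataFrame({"year": years, "month": 1, "day": 1}))
    offsets = rng.integers(0, 365, size=len(years))
    return pd.DatetimeIndex(start) + pd.to_timedelta(offsets, unit="D")


def generate_cohort(config: SyntheticConfig | None = None) -> SyntheticCohort:
    """Draw the covariate table and the latent per-person truth.

    The truth table carries each person's SC baseline date, age and eGFR at
    baseline, the true slope, and the first year of eMR coverage.  Covariate
    contributions to the slope are centered at their population means so the
    cohort-average true slope equals ``mean_slope``.
    """
    config = config or SyntheticConfig()
    config.validate()
    rng, _ = _rngs(config)
    n = config.n_persons

    person_id = np.array([f"P{i:06d}" for i in range(n)])
    sex = (rng.random(n) < config.male_fraction).astype(int)
    age0 = rng.uniform(config.age_min, config.age_max, n)
    smoking = (rng.random(n) < config.smoking_prevalence).astype(int)
    diabetes = (rng.random(n) < config.diabetes_prevalence).astype(int)
    bmi = np.clip(rng.normal(config.bmi_mean, config.bmi_sd, n), 15.0, 60.0)
    dosage = rng.binomial(2, config.allele_freq, n).astype(float)

    baseline_year = rng.choice(config.sc_visit_years, n)
    baseline_date = _random_dates_in_year(baseline_year, rng)
    birth = baseline_date - pd.to_timedelta(np.round(age0 * 365.25), unit="D")

    p_obese = float(stats.norm.sf((30.0 - config.bmi_mean) / config.bmi_sd))
    obese = (bmi >= 30.0).astype(int)
    slope = (
        config.mean_slope
        + config.age_effect * (age0 - (config.age_min + config.age_max) / 2.0)
        + config.male_effect * (sex - config.male_fraction)
        + config.smoking_effect * (smoking - config.smoking_prevalence)
        + config.obesity_effect * (obese - p_obese)
        + config.diabetes_effect * (diabetes - config.diabetes_prevalence)
        + config.variant_effect * (dosage - 2.0 * config.allele_freq)
        + rng.normal(0.0, config.slope_sd, n)
    )

    ln_crea0 = rng.normal(np.asarray(config.ln_crea_mean)[sex], config.ln_crea_sd, n)
    egfr0 = ckd_epi_2021(np.exp(ln_crea0), age0, sex)
    emr_start = rng.integers(config.emr_start_min, config.emr_start_max + 1, n)

    covariates = pd.DataFrame(
        {
            "person_id": person_id,
            "sex": sex,
            "birth_year": birth.year,
            "birth_month": birth.month,
            "smoking": smoking,
            "bmi": bmi,
            "diabetes": diabetes,
            "variant_dosage": dosage,
        }
    )
    truth = pd.DataFrame(
        {
            "person_id": person_id,
            "baseline_date": baseline_date,
            "age_at_baseline": age0,
            "egfr_baseline": np.asarray(egfr0, dtype=float),
            "slope": slope,
            "emr_start_year": emr_start,
        }
    )
    return SyntheticCohort(covariates=covariates, truth=truth)


def _latent_egfr(
    egfr0: np.ndarray,
    slope: np.ndarray,
    t_years: np.ndarray,
    aki_t: np.ndarray,
    config: SyntheticConfig,
) -> np.ndarray:
    """Latent eGFR at ``t_years`` since baseline, with the AKI episode shape."""
    eg = egfr0 - slope * t_years
    post = ~np.isnan(aki_t) & (t_years >= aki_t)
    if np.any(post):
        rec = np.clip((t_years[post] - aki_t[post]) / config.aki_recovery_years, 0.0, 1.0)
        eg[post] -= config.aki_drop * (1.0 - config.aki_recovery_frac * rec)
    return np.maximum(eg, config.egfr_floor)


def _draw_events(
    cohort: SyntheticCohort, config: SyntheticConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw sparse diagnostic events; returns the event table and per-person
    AKI offsets in years since baseline (NaN when no AKI)."""
    truth, cov = cohort.truth, cohort.covariates
    n = len(truth)
    window_start = pd.DatetimeIndex(
        pd.to_datetime(pd.DataFrame({"year": truth["emr_start_year"], "month": 1, "day": 1}))
    )
    window_end = pd.Timestamp(f"{config.year_end}-12-31")
    window_days = (window_end - window_start).days.to_numpy().astype(float)
    window_years = window_days / 365.25

    frames = []
    aki_t = np.full(n, np.nan)

    hazard_by_category = {
        "AKI": config.aki_hazard,
        "ESKD": config.eskd_hazard,
        "dialysis": config.dialysis_hazard,
        "transplant": config.transplant_hazard,
        "nephrectomy": config.nephrectomy_hazard,
    }
    for category, hazard in hazard_by_category.items():
        p = 1.0 - np.exp(-hazard * window_years)
        hit = rng.random(n) < p
        if not hit.any():
            continue
        offsets = rng.random(hit.sum()) * window_days[hit]
        dates = window_start[hit] + pd.to_timedelta(np.floor(offsets), unit="D")
        frames.append(
            pd.DataFrame(
                {
                    "person_id": truth.loc[hit, "person_id"].to_numpy(),
                    "event_date": dates,
                    "category": category,
                    "raw_code": _CATEGORY_CODES[category],
                }
            )
        )
        if category == "AKI":
            t = (
                (dates - pd.DatetimeIndex(truth.loc[hit, "baseline_date"])).days
                / 365.25
            )
            aki_t[np.flatnonzero(hit)] = t

    # pregnancy: women while younger than the configured maximum age
    female = cov["sex"].to_numpy() == 0
    age_at_window_start = (
        cohort.truth["age_at_baseline"].to_numpy()
        - (pd.DatetimeIndex(truth["baseline_date"]) - window_start).days / 365.25
    )
    eligible_years = np.clip(config.pregnancy_age_max - age_at_window_start, 0.0, window_years)
    p = np.where(female, 1.0 - np.exp(-config.pregnancy_hazard * eligible_years), 0.0)
    hit = rng.random(n) < p
    if hit.any():
        offsets = rng.random(hit.sum()) * eligible_years[hit] * 365.25
        dates = window_start[hit] + pd.to_timedelta(np.floor(offsets), unit="D")
        frames.append(
            pd.DataFrame(
                {
                    "person_id": truth.loc[hit, "person_id"].to_numpy(),
                    "event_date": dates,
                    "category": "pregnancy",
                    "raw_code": _CATEGORY_CODES["pregnancy"],
                }
            )
        )

    # diabetes codes for (most) persons with prevalent diabetes
    diabetic = cov["diabetes"].to_numpy() == 1
    hit = diabetic & (rng.random(n) < config.diabetes_code_prob)
    if hit.any():
        offsets = rng.random(hit.sum()) * window_days[hit]
        dates = window_start[hit] + pd.to_timedelta(np.floor(offsets), unit="D")
        frames.append(
            pd.DataFrame(
                {
                    "person_id": truth.loc[hit, "person_id"].to_numpy(),
                    "event_date": dates,
                    "category": "diabetes",
                    "raw_code": _CATEGORY_CODES["diabetes"],
                }
            )
        )

    if frames:
        events = pd.concat(frames, ignore_index=True)
        events = events.sort_values(["person_id", "event_date"]).reset_index(drop=True)
    else:
        events = pd.DataFrame(columns=["person_id", "event_date", "category", "raw_code"])
    return events, aki_t


def generate_measurements(
    cohort: SyntheticCohort, config: SyntheticConfig | None = None
) -> SyntheticData:
    """Simulate SC and raw eMR creatinine records plus diagnostic events.

    eMR visit counts follow an inhomogeneous Poisson process over calendar
    years whose intensity rises as the latent eGFR falls (reproducing the
    enrichment of sicker persons among high-count records); SC visits occur at
    baseline for everyone and at follow-up for a small random subset.  A
    configured fraction of corrupt eMR rows (duplicates, above-maximum,
    below-LOD values) is appended for QC exercising.
    """
    config = config or SyntheticConfig()
    config.validate()
    _, rng = _rngs(config)
    truth, cov = cohort.truth, cohort.covariates
    n = len(truth)

    events, aki_t = _draw_events(cohort, config, rng)

    baseline_date = pd.DatetimeIndex(truth["baseline_date"])
    egfr0 = truth["egfr_baseline"].to_numpy(float)
    slope = truth["slope"].to_numpy(float)
    age0 = truth["age_at_baseline"].to_numpy(float)
    sex = cov["sex"].to_numpy(int)
    emr_start = truth["emr_start_year"].to_numpy(int)

    # --- eMR visits: one Poisson draw per person-year -----------------------
    person_chunks, date_chunks = [], []
    for year in range(config.year_start, config.year_end + 1):
        active = emr_start <= year
        mid = pd.Timestamp(f"{year}-07-01")
        t_mid = (mid - baseline_date).days / 365.25
        eg = _latent_egfr(egfr0, slope, t_mid.to_numpy(), aki_t, config)
        if config.visit_intensity_active:
            lam = config.visit_base_rate * np.exp(
                config.visit_egfr_coef * np.clip(90.0 - eg, 0.0, None)
            )
        else:
            lam = np.full(n, config.visit_base_rate)
        lam = np.minimum(lam, config.visit_rate_cap) * active
        counts = rng.poisson(lam)
        total = int(counts.sum())
        if total == 0:
            continue
        idx = np.repeat(np.arange(n), counts)
        days = rng.integers(0, 365, total)
        dates = pd.Timestamp(f"{year}-01-01") + pd.to_timedelta(days, unit="D")
        person_chunks.append(idx)
        date_chunks.append(pd.DatetimeIndex(dates))

    if person_chunks:
        pidx = np.concatenate(person_chunks)
        pdates = date_chunks[0].append(date_chunks[1:])
        t = (pdates - baseline_date[pidx]).days / 365.25
        eg = _latent_egfr(egfr0[pidx], slope[pidx], t.to_numpy(), aki_t[pidx], config)
        crea_true = inverse_ckd_epi_2021(eg, age0[pidx] + t, sex[pidx])
        factor = true_bias_factor(pdates.year.to_numpy(), config.bias_schedule)
        eps = rng.normal(0.0, config.noise_sd, len(pidx)) if config.noise_sd > 0 else 0.0
        observed = crea_true / factor * np.exp(eps)
        emr = pd.DataFrame(
            {
                "person_id": truth["person_id"].to_numpy()[pidx],
                "exam_date": pdates,
                "value": observed,
                "source": EMR,
                "read_code": "44J3.",
                "qc_status": QcStatus.RAW,
            }
        )
    else:
        emr = pd.DataFrame(
            columns=["person_id", "exam_date", "value", "source", "read_code", "qc_status"]
        )

    # --- SC visits ----------------------------------------------------------
    def _sc_rows(mask: np.ndarray, dates: pd.DatetimeIndex) -> pd.DataFrame:
        t = (dates - baseline_date[mask]).days / 365.25
        eg = _latent_egfr(egfr0[mask], slope[mask], t.to_numpy(), aki_t[mask], config)
        crea_true = inverse_ckd_epi_2021(eg, age0[mask] + t, sex[mask])
        eps = rng.normal(0.0, config.noise_sd, int(mask.sum())) if config.noise_sd > 0 else 0.0
        return pd.DataFrame(
            {
                "person_id": truth["person_id"].to_numpy()[mask],
                "exam_date": dates,
                "value": crea_true * np.exp(eps),
                "source": SC,
                "read_code": "",
                "qc_status": QcStatus.PASS,
            }
        )

    all_mask = np.ones(n, dtype=bool)
    sc = _sc_rows(all_mask, baseline_date)
    baseline_year = baseline_date.year.to_numpy()
    last_visit_year = max(config.sc_visit_years)
    followup = (rng.random(n) < config.followup_fraction) & (baseline_year < last_visit_year)
    if followup.any():
        later = [
            rng.choice([y for y in config.sc_visit_years if y > by])
            for by in baseline_year[followup]
        ]
        fu_dates = _random_dates_in_year(np.asarray(later), rng)
        sc = pd.concat([sc, _sc_rows(followup, fu_dates)], ignore_index=True)

    # --- corrupt-row injection ---------------------------------------------
    m = len(emr)
    if m:
        n_dup = int(round(config.corrupt_duplicate_rate * m))
        n_hi = int(round(config.corrupt_above_max_rate * m))
        n_lo = int(round(config.corrupt_below_lod_rate * m))
        extras = []
        if n_dup:
            extras.append(emr.iloc[rng.integers(0, m, n_dup)])
        if n_hi:
            hi = emr.iloc[rng.integers(0, m, n_hi)].copy()
            hi["value"] = rng.uniform(7000.0, 9000.0, n_hi)
            extras.append(hi)
        if n_lo:
            lo = emr.iloc[rng.integers(0, m, n_lo)].copy()
            lo["value"] = rng.uniform(1.0, 9.0, n_lo)
            extras.append(lo)
        if extras:
            emr = pd.concat([emr, *extras], ignore_index=True)

    sc = sc.sort_values(["person_id", "exam_date"], kind="stable").reset_index(drop=True)
    emr = emr.reset_index(drop=True)
    return SyntheticData(
        covariates=cov, truth=truth, sc=sc, emr=emr, events=events
    )


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticData:
    """Convenience wrapper: cohort plus measurements in one call."""
    config = config or SyntheticConfig()
    return generate_measurements(generate_cohort(config), config)


def write_dataset(data: SyntheticData, out_dir) -> list[str]:
    """Write the simulated inputs in the formats consumed by records_io.

    Truth tables are written alongside with a ``truth_`` prefix; the raw-code
    column of the event table is emitted as ``code`` so the files exercise the
    code-list mapping on re-read.
    """
    from .records_io import write_codelist, write_outputs

    events_out = data.events.rename(columns={"raw_code": "code"})[
        ["person_id", "event_date", "code"]
    ]
    manifest = write_outputs(
        {
            "sc_creatinine": data.sc[["person_id", "exam_date", "value"]],
            "emr_creatinine": data.emr[["person_id", "exam_date", "value", "read_code"]],
            "events": events_out,
            "covariates": data.covariates,
            "truth_persons": data.truth,
        },
        out_dir,
    )
    from pathlib import Path

    write_codelist(Path(out_dir) / "codelist.yaml")
    return manifest + ["codelist.yaml"]
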