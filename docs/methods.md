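# Methods

## Error model and bias estimation

Serum creatinine from routine care (eMR) is treated as a noisy, systematically
shifted version of gold-standard study-center (SC) creatinine on the log
scale: `X* = X + s + E*` with `X = ln(crea_SC)`, `X* = ln(crea_eMR)`,
`E* ~ N(0, σ*²)` and a calendar-year-specific systematic term `s_year`. The
assumptions that matter:

* SC values are unbiased (single standardized enzymatic assay, one
  laboratory); they bypass QC and anchor the calibration.
* the systematic error is shared within a calendar year — the assay mix is
  unknown per measurement, so correction is valid **on average**, never for an
  individual value;
* pairing by person within a calendar year (eMR value closest in time to the
  SC draw, ties to the earlier date, one pair per SC visit) makes the
  estimator a paired contrast: person-level creatinine variation cancels, and
  `ŝ_year = mean ln(eMR) − mean ln(SC)` has standard error
  `√(2)·σ*/√n_pairs` rather than the much larger between-person spread.

The reported correction factor is `GM(SC)/GM(eMR) = exp(−ŝ_year)`; corrected
eMR = eMR × factor. A winsorized variant (clamping each log sample at its
within-year mean ± 3 SD before averaging) is provided as a robustness check;
it matters only when extreme outliers are present.

### Completing the table

Years lacking enough pairs receive proxies: interior gaps are interpolated
log-linearly between the flanking estimated years (a single-year gap is the
exponential of the mean of the two adjacent log biases); years before the
first estimated year carry its factor; years after the last estimated year
get factor 1.0 (no correction) when the last estimate is within
`unity_threshold` (default 0.05) of 1, otherwise they carry it. The
threshold generalizes the observation that assay standardization makes
recent years unbiased: extrapolating "no correction" is only safe when the
boundary estimate already sits near unity.

`min_pairs` (default 100) guards direct estimation. It is an absolute count
and must scale with the cohort: the simulation studies shipped with the
package run ~2,000 persons, roughly 1/200 of a biobank, and use
`min_pairs = 10` (`pipeline.SCALED_MIN_PAIRS`), which keeps every visit-year
estimable at that size while still rejecting single-digit samples.

## eGFR

CKD-EPI 2021 (race-free): `eGFR = 142 · min(Scr/κ,1)^α · max(Scr/κ,1)^−1.2 ·
0.9938^age · 1.012[female]`, Scr in mg/dL (µmol/L ÷ 88.42), κ = 0.7/0.9 and
α = −0.241/−0.302 for women/men. eGFR is not capped. Age at exam is
`(exam − birth)/365.25` with the birth day imputed as the 15th (biobank data
carry only year and month). CKD is flagged at eGFR < 60 mL/min/1.73m².
The generator uses the exact piecewise closed-form inverse (each branch has
a negative exponent, so the branch point `eGFR = 142·0.9938^age·[1.012]`
decides which branch to invert; no iteration).

## Censoring and decline

Assessments strictly after the earliest of {first AKI/ESKD/dialysis/
transplant/nephrectomy code, first eGFR < 15} are dropped; the triggering
low-eGFR assessment itself is kept (it defines onset). Assessments within
±183 days of a pregnancy code are dropped; diabetes codes never censor.
Eligibility for decline needs ≥2 surviving assessments spanning ≥365 days;
decline = (eGFR_first − eGFR_last)/years, so positive values mean loss.
This two-point estimator ignores intermediate assessments by construction,
which makes it insensitive to the informative visit process (visit timing
cannot bias a person's own endpoint difference under a linear latent path).
Cohort inference is the arithmetic mean ± 1.96·SE; regressions are
unweighted OLS over persons (assessment counts are surfaced as `m` but not
used as weights), with listwise deletion of missing covariates and loud
failure on zero-variance or collinear designs. Around AKI, the pre/post
assessments are those ≥183 days out minimizing the distance to 183 days,
and only *incident* AKI (first code after the person's first assessment)
qualifies.

## Synthetic data: what it emulates, and what it does not

Each person carries a latent linear eGFR path anchored at an SC baseline
(first SC visit uniform over {2007–2010, 2012, 2013}; a 4% subset gets a
second SC visit in a later year of that set). Baseline creatinine is
lognormal per sex (medians ~62/76 µmol/L, log-SD 0.15), converted to the
baseline eGFR via CKD-EPI 2021. True slopes are
`mean_slope + Σ β_j·(x_j − E[x_j]) + N(0, slope_sd)` with defaults
β_age = 0.005/yr, β_male = 0.10, β_smoking = 0.026, β_diabetes = 0.383,
β_variant = 0.052 per allele — magnitudes typical of biobank-scale decline
regressions — centered so the cohort mean decline equals `mean_slope`
(default 1.0 mL/min/1.73m²/yr). `slope_sd = 2.1` makes the realized SD of
per-person two-point declines ≈ 2.2, the dispersion biobank-scale decline
CIs and regression SEs imply; narrower person noise would make simulated
CIs unrealistically tight relative to calibration uncertainty.

eMR visits follow per-year Poisson counts with intensity
`0.5 · exp(0.03·max(0, 90 − eGFR))` per year (capped at 12) over a
person-specific window starting uniformly in 1990–2013 — sicker persons are
measured more often, reproducing the enrichment of low-eGFR persons among
high-count records. Observed eMR creatinine divides out the year's true
factor (0.84, 0.84, 0.90, 0.91, 0.93, 0.95, 0.97 over 2007–2013; 0.84
before, 1.0 after) and multiplies lognormal noise (log-SD 0.05); SC values
carry the same noise without bias. AKI appears as an abrupt 20-unit eGFR
drop with 70% recovery over a year; other kidney events are plain dated
codes with small constant hazards. A small fraction of corrupt rows
(duplicates, >6524 µmol/L, sub-LOD values) exercises QC.

Deliberately *not* emulated: calendar trends in recording volume, multiple
AKI episodes, assay-level (rather than year-level) error structure,
non-linear trajectories, correlated covariates, and real read-code
vocabularies (the shipped code list is an illustrative stub; users supply
their own). Passing tests therefore show the pipeline recovers truth under
the stated error model at realistic noise — not that any particular real
dataset satisfies that model.

### Known small-sample behaviour

With ~120 pairs per estimated year (2,000 persons), each factor carries a
standard error ≈ 0.006 on the log scale. Because the first estimated year's
factor is carried to *all* earlier calendar years — where roughly two thirds
of first assessments fall — its estimation error is shared across persons
and propagates to the cohort mean decline with a weight of ≈3.5, adding a
seed-level SD of ≈ 0.025 that the within-cohort CI cannot see. At biobank
scale (10⁴–10⁵ pairs/year) this term is negligible; at a few hundred persons
it dominates. Correcting with the true factor schedule instead of estimates
removes it entirely (mean 1.0015, seed SD 0.018 over 25 cohorts), confirming
the pipeline itself is unbiased.

## Numerical and design choices

* Dates are ISO 8601; "±6 months" is ±183 days; "one year apart" is ≥365
  days — unambiguous and reproducible.
* Duplicates are identical (person, date, value) triples; same-day differing
  values are kept as plausibly distinct draws. Deduplication precedes LoQ
  flooring and happens after read-code mapping.
* Default LOD = LoQ = 18 µmol/L are laboratory-specific placeholders; the
  hard maximum is 6524 µmol/L.
* Factors are kept at full precision internally and rounded to two decimals
  only for display.
* The regression covariate "age" is age at *first assessment* (centered at
  40), while the generator ties the slope to age at SC entry; for eMR members
  the first assessment predates entry by years, so the simulated age
  coefficient attenuates relative to its programmed value. This mirrors the
  covariate-timing mismatch of real baseline questionnaires and is why
  recovery tests target the exactly-observed covariates (sex, smoking,
  diabetes, variant dosage).
* Incident events are defined as the first record of a category dated
  strictly after the person's first assessment.
* Simulation sizes shipped with the tests: 2,000 persons per cohort, 50
  cohorts for the calibration studies, 5,000 pairs/year for factor-recovery
  Monte Carlo.

## Limitations

The correction is valid in expectation only; person-level corrected values
remain noisy and possibly assay-shifted. Extrapolated factors (before the
first estimable year) inherit that year's error across a potentially long
past. The two-point decline ignores within-person non-linearity and gives
every person equal weight regardless of span or assessment count. No
mixed-effects trajectory modelling, no cystatin-C equations, and no
continuous-in-time (assay-vintage) error model are attempted.
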