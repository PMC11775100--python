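"""Annualized decline, cohort mean/CI, regressions and peri-AKI selection."""

import numpy as np
import pandas as pd
import pytest

from egfrtraj.decline import (
    aki_peri_decline,
    annual_decline,
    decline_regression,
    mean_decline_ci,
)
from egfrtraj.records_io import EMR

from .conftest import assessment_frame, event_frame


def trajectory(person, points):
    """points: iterable of (date, egfr)."""
    return assessment_frame([(person, d, e) for d, e in points], source=EMR)


class TestAnnualDecline:
    def test_ten_units_over_five_years(self):
        traj = trajectory("A", [("2005-01-01", 100.0), ("2010-01-01", 90.0)])
        out = annual_decline(traj)
        assert out["eligible"].iloc[0]
        assert out["decline"].iloc[0] == pytest.approx(2.0, rel=1e-3)

    def test_six_month_span_ineligible(self):
        traj = trajectory("A", [("2005-01-01", 100.0), ("2005-07-01", 90.0)])
        out = annual_decline(traj)
        assert not out["eligible"].iloc[0]
        assert out["reason"].iloc[0] == "span_lt_1yr"

    def test_single_assessment_ineligible(self):
        out = annual_decline(trajectory("A", [("2005-01-01", 100.0)]))
        assert out["reason"].iloc[0] == "single_assessment"

    def test_constant_egfr_zero_decline(self):
        traj = trajectory("A", [("2005-01-01", 90.0), ("2008-01-01", 90.0)])
        assert annual_decline(traj)["decline"].iloc[0] == 0.0

    def test_endpoints_only(self):
        """Intermediate assessments never change the estimate."""
        sparse = trajectory("A", [("2005-01-01", 100.0), ("2010-01-01", 80.0)])
        dense = trajectory(
            "A",
            [("2005-01-01", 100.0), ("2006-06-01", 55.0), ("2008-01-01", 120.0),
             ("2010-01-01", 80.0)],
        )
        assert annual_decline(dense)["decline"].iloc[0] == pytest.approx(
            annual_decline(sparse)["decline"].iloc[0]
        )

    def test_positive_means_falling_egfr(self):
        falling = trajectory("A", [("2005-01-01", 100.0), ("2007-01-01", 80.0)])
        rising = trajectory("B", [("2005-01-01", 80.0), ("2007-01-01", 100.0)])
        assert annual_decline(falling)["decline"].iloc[0] > 0
        assert annual_decline(rising)["decline"].iloc[0] < 0


class TestMeanCi:
    def test_identical_values_zero_width(self):
        mean, lo, hi = mean_decline_ci([1.0, 1.0, 1.0])
        assert (mean, lo, hi) == (1.0, 1.0, 1.0)

    def test_two_values(self):
        mean, lo, hi = mean_decline_ci([0.0, 2.0])
        assert mean == 1.0 and lo < mean < hi

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            mean_decline_ci([1.0])

    def test_nominal_coverage_of_true_mean(self):
        """mean +/- 1.96 SE covers the true mean ~95% of the time."""
        rng = np.random.default_rng(99)
        hits = 0
        n_seeds, n = 500, 40
        for _ in range(n_seeds):
            x = rng.normal(1.0, 0.8, n)
            _, lo, hi = mean_decline_ci(x)
            hits += lo <= 1.0 <= hi
        assert 0.92 <= hits / n_seeds <= 0.98


def person_table(declines, ages=None):
    n = len(declines)
    return pd.DataFrame(
        {
            "person_id": [f"P{i}" for i in range(n)],
            "eligible": True,
            "decline": declines,
            "n_assessments": 2,
            "age_first": ages if ages is not None else np.linspace(40.0, 70.0, n),
            "first_date": pd.Timestamp("2005-01-01"),
        }
    )


def covariate_table(n, rng=None, **overrides):
    rng = rng or np.random.default_rng(0)
    cov = pd.DataFrame(
        {
            "person_id": [f"P{i}" for i in range(n)],
            "sex": rng.integers(0, 2, n),
            "smoking": rng.integers(0, 2, n),
            "bmi": rng.uniform(20, 40, n),
            "diabetes": rng.integers(0, 2, n),
            "variant_dosage": rng.binomial(2, 0.2, n).astype(float),
        }
    )
    for key, value in overrides.items():
        cov[key] = value
    return cov


class TestRegression:
    def test_exact_recovery_without_noise(self):
        rng = np.random.default_rng(5)
        n = 200
        ages = rng.uniform(40, 70, n)
        cov = covariate_table(n, rng)
        declines = 0.9 + 0.005 * (ages - 40.0)
        table = decline_regression(person_table(declines, ages), cov, "lifestyle")
        by = table.set_index("term")["beta"]
        assert by["intercept"] == pytest.approx(0.9, abs=1e-9)
        assert by["age_centered"] == pytest.approx(0.005, abs=1e-9)
        for term in ("sex", "smoking", "obesity", "diabetes"):
            assert by[term] == pytest.approx(0.0, abs=1e-9)

    def test_zero_variance_covariate_fails_loudly(self):
        cov = covariate_table(50, diabetes=1)
        with pytest.raises(ValueError, match="diabetes"):
            decline_regression(
                person_table(np.random.default_rng(1).normal(1, 0.3, 50)), cov, "lifestyle"
            )

    def test_collinear_design_fails_loudly(self):
        rng = np.random.default_rng(2)
        n = 80
        cov = covariate_table(n, rng)
        cov["variant_dosage"] = cov["sex"].astype(float)  # exact copy of sex
        with pytest.raises(ValueError, match="collinear"):
            decline_regression(person_table(rng.normal(1, 0.3, n)), cov, "genetic")

    def test_listwise_deletion_of_missing_covariates(self):
        rng = np.random.default_rng(3)
        n = 60
        cov = covariate_table(n, rng)
        cov.loc[:9, "bmi"] = np.nan
        table = decline_regression(person_table(rng.normal(1, 0.3, n)), cov, "lifestyle")
        assert table["n_persons"].iloc[0] == n - 10

    def test_permuted_outcome_covers_zero(self):
        """With the outcome shuffled, non-intercept CIs should cover zero in
        at least 90% of replicates."""
        rng = np.random.default_rng(11)
        n = 300
        cov = covariate_table(n, rng)
        declines = rng.normal(1.0, 0.5, n)
        hits, total = 0, 0
        for _ in range(30):
            shuffled = rng.permutation(declines)
            table = decline_regression(person_table(shuffled), cov, "lifestyle")
            body = table[table["term"] != "intercept"]
            hits += int(((body["ci_low"] <= 0) & (body["ci_high"] >= 0)).sum())
            total += len(body)
        assert hits / total >= 0.90


class TestPeriAki:
    def test_selects_closest_to_six_months_each_side(self):
        aki = pd.Timestamp("2010-01-01")
        points = [
            (aki - pd.DateOffset(months=12), 100.0),
            (aki - pd.DateOffset(months=7), 95.0),
            (aki + pd.DateOffset(months=8), 80.0),
            (aki + pd.DateOffset(months=20), 75.0),
        ]
        traj = trajectory("A", [(d.strftime("%Y-%m-%d"), e) for d, e in points])
        events = event_frame([("A", "2010-01-01", "AKI")])
        *_, table = aki_peri_decline(traj, events)
        row = table.iloc[0]
        assert row["egfr_before"] == 95.0
        assert row["egfr_after"] == 80.0

    def test_missing_qualifying_side_excludes_person(self):
        aki = pd.Timestamp("2010-01-01")
        points = [(aki - pd.DateOffset(months=3), 95.0), (aki + pd.DateOffset(months=8), 80.0)]
        traj = trajectory("A", [(d.strftime("%Y-%m-%d"), e) for d, e in points])
        events = event_frame([("A", "2010-01-01", "AKI")])
        mean, lo, hi, n, table = aki_peri_decline(traj, events)
        assert n == 0 and table.empty

    def test_only_incident_aki_counts(self):
        """An AKI recorded before the first assessment is not incident."""
        traj = trajectory(
            "A", [("2010-01-01", 95.0), ("2012-01-01", 85.0), ("2013-06-01", 80.0)]
        )
        events = event_frame([("A", "2009-01-01", "AKI")])
        *_, table = aki_peri_decline(traj, events)
        assert table.empty

    def test_simulated_aki_raises_peri_event_decline(self, small_dataset):
        from egfrtraj.pipeline import run_synthetic_study

        res = run_synthetic_study(data=small_dataset)
        assert res.aki_n > 0
        assert res.aki_mean > res.mean_decline
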