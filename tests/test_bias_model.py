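"""Pairing, per-year bias estimation, table completion and correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from egfrtraj.bias_model import (
    Provenance,
    apply_bias_correction,
    build_bias_table,
    estimate_year_bias,
    pair_same_year,
)
from egfrtraj.records_io import EMR, SC

from .conftest import creatinine_frame


def make_pairs(sc_values, emr_values, year=2008):
    return pd.DataFrame(
        {
            "person_id": [f"P{i}" for i in range(len(sc_values))],
            "year": year,
            "sc_date": pd.Timestamp(f"{year}-06-01"),
            "emr_date": pd.Timestamp(f"{year}-06-15"),
            "sc_value": np.asarray(sc_values, float),
            "emr_value": np.asarray(emr_values, float),
        }
    )


def simulate_pairs(factor, n, seed, year=2008, mu=np.log(75.0), sigma=0.25, noise=0.05):
    """Lognormal SC values; eMR = SC / factor with lognormal noise."""
    rng = np.random.default_rng(seed)
    sc = np.exp(rng.normal(mu, sigma, n))
    emr = sc / factor * np.exp(rng.normal(0.0, noise, n))
    return make_pairs(sc, emr, year)


class TestPairing:
    def test_closest_in_time_wins(self):
        sc = creatinine_frame([("A", "2008-06-01", 70.0)], source=SC)
        emr = creatinine_frame(
            [("A", "2008-05-20", 80.0), ("A", "2008-09-01", 90.0)], source=EMR
        )
        pairs, _ = pair_same_year(sc, emr)
        assert len(pairs) == 1
        assert pairs["emr_date"].iloc[0] == pd.Timestamp("2008-05-20")

    def test_tie_broken_by_earlier_date(self):
        sc = creatinine_frame([("A", "2008-06-10", 70.0)], source=SC)
        emr = creatinine_frame(
            [("A", "2008-06-05", 80.0), ("A", "2008-06-15", 90.0)], source=EMR
        )
        pairs, _ = pair_same_year(sc, emr)
        assert pairs["emr_date"].iloc[0] == pd.Timestamp("2008-06-05")

    def test_different_calendar_year_never_pairs(self):
        sc = creatinine_frame([("A", "2008-01-05", 70.0)], source=SC)
        emr = creatinine_frame([("A", "2006-12-28", 80.0)], source=EMR)
        pairs, _ = pair_same_year(sc, emr)
        assert pairs.empty

    def test_pair_count_on_five_person_fixture(self):
        sc = creatinine_frame(
            [(p, "2008-06-01", 70.0) for p in "ABCDE"], source=SC
        )
        emr = creatinine_frame(
            [("A", "2008-03-01", 75.0), ("B", "2008-07-01", 76.0),
             ("C", "2008-11-30", 77.0), ("D", "2007-06-01", 78.0),
             ("E", "2009-06-01", 79.0)],
            source=EMR,
        )
        pairs, stats = pair_same_year(sc, emr)
        assert len(pairs) == 3
        assert stats.loc[stats["year"] == 2008, "n_pairs"].iloc[0] == 3


class TestEstimation:
    def test_identical_values_give_unity(self):
        pairs = make_pairs([60.0, 80.0, 100.0], [60.0, 80.0, 100.0])
        est = estimate_year_bias(pairs, min_pairs=1)
        assert est["factor"].iloc[0] == pytest.approx(1.0)

    def test_constructed_factor_recovered_exactly(self):
        sc = np.array([60.0, 80.0, 100.0])
        pairs = make_pairs(sc, sc / 0.84)
        est = estimate_year_bias(pairs, min_pairs=1)
        assert est["factor"].iloc[0] == pytest.approx(0.84, abs=1e-12)

    def test_monte_carlo_recovery_at_5000_pairs(self):
        pairs = simulate_pairs(0.90, n=5000, seed=11)
        est = estimate_year_bias(pairs, min_pairs=100)
        assert est["factor"].iloc[0] == pytest.approx(0.90, abs=0.01)

    def test_winsorizing_tames_a_100x_outlier(self):
        clean = simulate_pairs(0.90, n=500, seed=3)
        clean_factor = estimate_year_bias(clean, min_pairs=1)["factor"].iloc[0]
        spoiled = clean.copy()
        spoiled.loc[0, "emr_value"] *= 100.0
        raw = estimate_year_bias(spoiled, min_pairs=1)["factor"].iloc[0]
        robust = estimate_year_bias(spoiled, winsorize=True, min_pairs=1)["factor"].iloc[0]
        assert abs(robust - clean_factor) < abs(raw - clean_factor)

    def test_years_below_min_pairs_are_skipped(self):
        pairs = pd.concat(
            [simulate_pairs(0.9, 150, 1, year=2008), simulate_pairs(0.95, 10, 2, year=2012)],
            ignore_index=True,
        )
        est = estimate_year_bias(pairs, min_pairs=100)
        assert est["year"].tolist() == [2008]

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.floats(min_value=0.01, max_value=100.0, allow_nan=False))
    def test_scale_equivariance(self, scale):
        pairs = simulate_pairs(0.88, n=200, seed=5)
        base = estimate_year_bias(pairs, min_pairs=1)["factor"].iloc[0]
        scaled = pairs.assign(
            sc_value=pairs["sc_value"] * scale, emr_value=pairs["emr_value"] * scale
        )
        rescaled = estimate_year_bias(scaled, min_pairs=1)["factor"].iloc[0]
        assert rescaled == pytest.approx(base, rel=1e-9)


def estimates_from(factors: dict[int, float], n_pairs=500):
    return pd.DataFrame(
        {
            "year": list(factors),
            "factor": list(factors.values()),
            "log_bias": [-np.log(f) for f in factors.values()],
            "n_pairs": n_pairs,
            "provenance": Provenance.ESTIMATED,
        }
    )


class TestBiasTable:
    def test_single_gap_uses_exp_mean_of_logs(self):
        table = build_bias_table(estimates_from({2010: 0.91, 2012: 0.95}))
        row = table[table["year"] == 2011].iloc[0]
        assert round(row["factor"], 2) == 0.93
        assert row["provenance"] == Provenance.INTERPOLATED

    def test_years_before_first_carry_first_factor(self):
        table = build_bias_table(
            estimates_from({2007: 0.84, 2010: 0.91}), year_span=(1999, 2010)
        )
        row = table[table["year"] == 1999].iloc[0]
        assert row["factor"] == pytest.approx(0.84)
        assert row["provenance"] == Provenance.BOUNDARY_CARRY

    def test_years_after_last_become_unity_when_close(self):
        table = build_bias_table(
            estimates_from({2012: 0.95, 2013: 0.97}), year_span=(2012, 2015)
        )
        row = table[table["year"] == 2015].iloc[0]
        assert row["factor"] == 1.0
        assert row["provenance"] == Provenance.UNITY

    def test_years_after_last_carry_when_far_from_unity(self):
        table = build_bias_table(
            estimates_from({2012: 0.80}), year_span=(2012, 2015)
        )
        row = table[table["year"] == 2015].iloc[0]
        assert row["factor"] == pytest.approx(0.80)
        assert row["provenance"] == Provenance.BOUNDARY_CARRY

    def test_equal_flanking_factors_interpolate_to_same(self):
        table = build_bias_table(estimates_from({2008: 0.9, 2011: 0.9}))
        inner = table[table["year"].isin([2009, 2010])]
        assert np.allclose(inner["factor"], 0.9)

    def test_multi_year_gap_is_log_linear(self):
        table = build_bias_table(estimates_from({2008: 0.8, 2011: 1.0}))
        factors = table.set_index("year")["factor"]
        expected_2009 = np.exp(np.log(0.8) + (np.log(1.0) - np.log(0.8)) / 3)
        assert factors[2009] == pytest.approx(expected_2009)
        assert factors[2010] == pytest.approx(np.exp(np.log(0.8) + 2 * (0 - np.log(0.8)) / 3))

    def test_empty_estimates_rejected(self):
        with pytest.raises(ValueError, match="zero estimated years"):
            build_bias_table(estimates_from({}))


class TestCorrection:
    def test_multiplicative_correction(self):
        emr = creatinine_frame([("A", "2007-05-01", 100.0)])
        table = build_bias_table(estimates_from({2007: 0.84}))
        out = apply_bias_correction(emr, table)
        assert out["value_corrected"].iloc[0] == pytest.approx(84.0)

    def test_unity_year_left_unchanged(self):
        emr = creatinine_frame([("A", "2015-05-01", 100.0)])
        table = build_bias_table(
            estimates_from({2012: 0.95, 2013: 0.97}), year_span=(2012, 2016)
        )
        out = apply_bias_correction(emr, table)
        assert out["value_corrected"].iloc[0] == 100.0

    def test_uncovered_year_raises_with_year_named(self):
        emr = creatinine_frame([("A", "1995-05-01", 100.0)])
        table = build_bias_table(estimates_from({2007: 0.84}))
        with pytest.raises(ValueError, match="1995"):
            apply_bias_correction(emr, table)

    def test_round_trip_reestimation_is_exactly_unity(self):
        pairs = simulate_pairs(0.88, n=400, seed=9, year=2008)
        est = estimate_year_bias(pairs, min_pairs=1)
        factor = est["factor"].iloc[0]
        corrected = pairs.assign(emr_value=pairs["emr_value"] * factor)
        again = estimate_year_bias(corrected, min_pairs=1)["factor"].iloc[0]
        assert again == pytest.approx(1.0, abs=1e-12)
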