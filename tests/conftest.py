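"""Shared fixtures: tiny hand-built tables and one module-scope synthetic run."""

import numpy as np
import pandas as pd
import pytest

from egfrtraj.records_io import EMR, SC, QcStatus
from egfrtraj.synthetic_data import SyntheticConfig, generate_dataset


def creatinine_frame(rows, source=EMR):
    """Build a creatinine record frame from (person, date, value[, code]) rows."""
    out = pd.DataFrame(rows, columns=["person_id", "exam_date", "value"])
    out["exam_date"] = pd.to_datetime(out["exam_date"])
    out["source"] = source
    out["read_code"] = "44J3."
    out["qc_status"] = QcStatus.PASS if source == SC else QcStatus.RAW
    return out


def event_frame(rows):
    """Build an event frame from (person, date, category) rows."""
    out = pd.DataFrame(rows, columns=["person_id", "event_date", "category"])
    out["event_date"] = pd.to_datetime(out["event_date"])
    out["raw_code"] = "x"
    return out


def assessment_frame(rows, source=SC, sex=0, age=55.0):
    """Build an eGFR assessment frame from (person, date, egfr) rows."""
    out = pd.DataFrame(rows, columns=["person_id", "exam_date", "egfr"])
    out["exam_date"] = pd.to_datetime(out["exam_date"])
    out["source"] = source
    out["creatinine"] = 70.0
    out["age_at_exam"] = age
    out["sex"] = sex
    out["ckd"] = out["egfr"] < 60
    out["bias_corrected"] = False
    return out


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic dataset reused by read-only tests."""
    return generate_dataset(SyntheticConfig(n_persons=600, seed=20))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
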