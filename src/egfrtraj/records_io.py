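"""Reading and writing the pipeline's tabular inputs and outputs.

Four person-level input tables are consumed:

* study-center (SC) serum creatinine: ``person_id, exam_date, value`` (µmol/L);
* EHR (eMR) serum creatinine: ``person_id, exam_date, value, read_code``;
* diagnostic events: ``person_id, event_date, code`` — raw read codes are
  mapped to kidney-relevant categories via a configurable code list;
* baseline covariates: sex, birth year/month, smoking, BMI, diabetes and the
  allele dosage of a decline-associated genetic variant.

All tables are UTF-8 delimited text (TSV by default, CSV accepted via the
``.csv`` suffix) with a header row and ISO-8601 dates.  Outputs are written in
the same format so that read -> write -> read round-trips are lossless.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping

import pandas as pd
import yaml

__all__ = [
    "SC",
    "EMR",
    "QcStatus",
    "EVENT_CATEGORIES",
    "KIDNEY_CENSOR_CATEGORIES",
    "DEFAULT_CODELIST",
    "TableFormatError",
    "InputTables",
    "load_codelist",
    "write_codelist",
    "map_event_codes",
    "read_sc_creatinine",
    "read_emr_creatinine",
    "read_events",
    "read_covariates",
    "read_tables",
    "write_table",
    "read_table",
    "write_outputs",
    "config_hash",
]

log = logging.getLogger(__name__)

#: Source labels for creatinine measurements.
SC = "SC"
EMR = "eMR"


class QcStatus:
    """String constants for the quality-control status of a creatinine record."""

    RAW = "raw"
    PASS = "pass"
    EXCLUDED_DUPLICATE = "excluded_duplicate"
    EXCLUDED_BELOW_LOD = "excluded_below_lod"
    EXCLUDED_ABOVE_MAX = "excluded_above_max"
    EXCLUDED_NONNUMERIC = "excluded_nonnumeric"
    FLOORED_TO_LOQ = "floored_to_loq"

    #: Statuses under which a record is usable downstream.
    KEPT = (PASS, FLOORED_TO_LOQ)
    ALL = (
        RAW,
        PASS,
        EXCLUDED_DUPLICATE,
        EXCLUDED_BELOW_LOD,
        EXCLUDED_ABOVE_MAX,
        EXCLUDED_NONNUMERIC,
        FLOORED_TO_LOQ,
    )


#: Diagnostic-event categories recognised by the pipeline.
EVENT_CATEGORIES = (
    "AKI",
    "ESKD",
    "transplant",
    "dialysis",
    "nephrectomy",
    "pregnancy",
    "diabetes",
)

#: Categories whose first occurrence censors a person's later assessments
#: (severe kidney disease, renal replacement therapy, nephrectomy).
KIDNEY_CENSOR_CATEGORIES = ("AKI", "ESKD", "transplant", "dialysis", "nephrectomy")

#: Small illustrative code list.  Real analyses substitute their own mapping
#: of primary-care read codes to categories via a YAML file.
DEFAULT_CODELIST: dict[str, str] = {
    "K04z.": "AKI",
    "K04y.": "AKI",
    "K050.": "ESKD",
    "K055.": "ESKD",
    "7B00.": "transplant",
    "7B002": "transplant",
    "7L1A.": "dialysis",
    "7L1A0": "dialysis",
    "7B06.": "nephrectomy",
    "7B061": "nephrectomy",
    "62...": "pregnancy",
    "6221.": "pregnancy",
    "C10..": "diabetes",
    "C109.": "diabetes",
}

#: Plausible exam-date range; rows outside it are treated as technical errors.
DATE_RANGE = (pd.Timestamp("1900-01-01"), pd.Timestamp("2030-12-31"))


class TableFormatError(ValueError):
    """A required column is missing or a cell cannot be parsed."""


@dataclass
class InputTables:
    """The four parsed input tables plus bookkeeping from parsing."""

    sc: pd.DataFrame
    emr: pd.DataFrame
    events: pd.DataFrame
    covariates: pd.DataFrame
    n_unmapped_events: int = 0


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_raw(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    return pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, required: Mapping[str, tuple[str, ...]], path) -> dict[str, str]:
    """Resolve each canonical column to the first matching alias present.

    Returns a canonical-name -> actual-name mapping; raises
    :class:`TableFormatError` naming the column and file otherwise.
    """
    resolved = {}
    for canonical, aliases in required.items():
        for alias in aliases:
            if alias in df.columns:
                resolved[canonical] = alias
                break
        else:
            raise TableFormatError(
                f"missing required column '{canonical}' "
                f"(accepted names: {', '.join(aliases)}) in {path}"
            )
    return resolved


def _parse_dates(raw: pd.Series, path, column: str) -> pd.Series:
    """Parse ISO-8601 dates; empty cells become NaT, malformed cells raise."""
    stripped = raw.str.strip()
    missing = stripped == ""
    parsed = pd.to_datetime(stripped.where(~missing), format="ISO8601", errors="coerce")
    bad = parsed.isna() & ~missing
    if bad.any():
        row = int(bad.idxmax())
        raise TableFormatError(
            f"unparseable date '{raw.iloc[row]}' in column '{column}' "
            f"of {path} at row index {row}"
        )
    return parsed


def default_technical_error(values: pd.Series, dates: pd.Series) -> pd.Series:
    """Default predicate marking technical errors in raw eMR creatinine rows.

    A row is a technical error when its value is non-numeric or non-positive,
    or its date is missing or outside the plausible range.
    """
    numeric = pd.to_numeric(values, errors="coerce")
    bad_value = numeric.isna() | (numeric <= 0)
    bad_date = dates.isna() | (dates < DATE_RANGE[0]) | (dates > DATE_RANGE[1])
    return bad_value | bad_date


def load_codelist(path: str | Path) -> dict[str, str]:
    """Load a raw-code -> category mapping from a YAML file."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh) or {}
    bad = {c for c in mapping.values() if c not in EVENT_CATEGORIES}
    if bad:
        raise TableFormatError(f"unknown event categories in code list {path}: {sorted(bad)}")
    return {str(k): str(v) for k, v in mapping.items()}


def write_codelist(path: str | Path, codelist: Mapping[str, str] | None = None) -> None:
    codelist = DEFAULT_CODELIST if codelist is None else dict(codelist)
    with open(path, "w") as fh:
        yaml.safe_dump(codelist, fh, sort_keys=True)


def read_sc_creatinine(path: str | Path) -> pd.DataFrame:
    """Read the study-center creatinine table.

    SC values are gold standard (one assay, one laboratory) and bypass QC:
    they are returned with ``qc_status='pass'``.  Non-numeric or non-positive
    values raise, since the central table is expected to be clean.
    """
    path = Path(path)
    raw = _read_raw(path)
    cols = _require_columns(
        raw,
        {"person_id": ("person_id",), "exam_date": ("exam_date", "date"),
         "value": ("value", "creatinine")},
        path,
    )
    dates = _parse_dates(raw[cols["exam_date"]], path, cols["exam_date"])
    values = pd.to_numeric(raw[cols["value"]], errors="coerce")
    bad = values.isna() | (values <= 0) | dates.isna()
    if bad.any():
        row = int(bad.idxmax())
        raise TableFormatError(
            f"non-positive, non-numeric or undated SC creatinine in {path} at row index {row}"
        )
    return pd.DataFrame(
        {
            "person_id": raw[cols["person_id"]].astype(str),
            "exam_date": dates,
            "value": values.astype(float),
            "source": SC,
            "read_code": "",
            "qc_status": QcStatus.PASS,
        }
    )


def read_emr_creatinine(
    path: str | Path,
    technical_error: Callable[[pd.Series, pd.Series], pd.Series] | None = None,
) -> pd.DataFrame:
    """Read the raw eMR creatinine table.

    Rows flagged by the (pluggable) ``technical_error`` predicate are kept with
    ``qc_status='excluded_nonnumeric'`` so QC reports can account for every raw
    row; all other rows enter with status ``raw``.
    """
    path = Path(path)
    raw = _read_raw(path)
    cols = _require_columns(
        raw,
        {"person_id": ("person_id",), "exam_date": ("exam_date", "event_date", "date"),
         "value": ("value", "creatinine")},
        path,
    )
    code_col = "read_code" if "read_code" in raw.columns else None
    dates = _parse_dates(raw[cols["exam_date"]], path, cols["exam_date"])
    values_raw = raw[cols["value"]]
    predicate = technical_error or default_technical_error
    bad = predicate(values_raw, dates).astype(bool)
    values = pd.to_numeric(values_raw, errors="coerce")
    df = pd.DataFrame(
        {
            "person_id": raw[cols["person_id"]].astype(str),
            "exam_date": dates,
            "value": values.astype(float),
            "source": EMR,
            "read_code": raw[code_col].astype(str) if code_col else "",
            "qc_status": QcStatus.RAW,
        }
    )
    df.loc[bad, "qc_status"] = QcStatus.EXCLUDED_NONNUMERIC
    return df


def map_event_codes(events: pd.DataFrame, codelist: Mapping[str, str]) -> tuple[pd.DataFrame, int]:
    """Map raw read codes to event categories; drop and count unmapped codes.

    Categorisation is a pure function of ``(raw_code, codelist)``.  Duplicate
    ``(person, date, category)`` rows are collapsed to one.
    """
    out = events.copy()
    out["category"] = out["raw_code"].map(dict(codelist))
    n_unmapped = int(out["category"].isna().sum())
    if n_unmapped:
        log.info("dropping %d events with unmapped read codes", n_unmapped)
    out = out.dropna(subset=["category"])
    out = out.drop_duplicates(subset=["person_id", "event_date", "category"], keep="first")
    return out.reset_index(drop=True), n_unmapped


def read_events(
    path: str | Path, codelist: Mapping[str, str] | None = None
) -> tuple[pd.DataFrame, int]:
    """Read the diagnostic-event table and map codes to categories."""
    path = Path(path)
    raw = _read_raw(path)
    cols = _require_columns(
        raw,
        {"person_id": ("person_id",), "event_date": ("event_date", "exam_date", "date"),
         "raw_code": ("code", "raw_code", "read_code")},
        path,
    )
    dates = _parse_dates(raw[cols["event_date"]], path, cols["event_date"])
    df = pd.DataFrame(
        {
            "person_id": raw[cols["person_id"]].astype(str),
            "event_date": dates,
            "raw_code": raw[cols["raw_code"]].astype(str),
        }
    )
    df = df.dropna(subset=["event_date"])  # events require a date
    return map_event_codes(df, DEFAULT_CODELIST if codelist is None else codelist)


_COVARIATE_NUMERIC = ("sex", "birth_year", "birth_month", "smoking", "bmi", "diabetes", "variant_dosage")


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read the baseline covariate table; optional covariates may be missing."""
    path = Path(path)
    raw = _read_raw(path)
    cols = _require_columns(
        raw,
        {"person_id": ("person_id",), "sex": ("sex",),
         "birth_year": ("birth_year",), "birth_month": ("birth_month",)},
        path,
    )
    df = pd.DataFrame({"person_id": raw[cols["person_id"]].astype(str)})
    for col in _COVARIATE_NUMERIC:
        source = cols.get(col, col)
        if source in raw.columns:
            df[col] = pd.to_numeric(raw[source].replace("", None), errors="coerce")
        else:
            df[col] = float("nan")
    if df["sex"].dropna().isin([0, 1]).all() is False:
        raise TableFormatError(f"sex must be coded 0 (female) / 1 (male) in {path}")
    dosage = df["variant_dosage"].dropna()
    if ((dosage < 0) | (dosage > 2)).any():
        raise TableFormatError(f"variant_dosage outside [0, 2] in {path}")
    return df


def read_tables(
    paths: Mapping[str, str | Path],
    codelist: Mapping[str, str] | None = None,
) -> InputTables:
    """Read the four input tables.

    ``paths`` maps the keys ``sc``, ``emr``, ``events`` and ``covariates`` to
    file paths; ``codelist`` defaults to the illustrative built-in mapping.
    """
    sc = read_sc_creatinine(paths["sc"])
    emr = read_emr_creatinine(paths["emr"])
    events, n_unmapped = read_events(paths["events"], codelist)
    covariates = read_covariates(paths["covariates"])
    return InputTables(sc=sc, emr=emr, events=events, covariates=covariates,
                       n_unmapped_events=n_unmapped)


# ---------------------------------------------------------------------------
# output side

def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a DataFrame as delimited text with ISO dates, full float precision."""
    path = Path(path)
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep=_sep_for(path), index=False, float_format="%.12g")
    return path


def read_table(path: str | Path, date_columns: tuple[str, ...] = ("exam_date", "event_date")) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if "person_id" in df.columns:
        df["person_id"] = df["person_id"].astype(str)
    for col in date_columns:
        if col in df.columns:
            df[col] = pd.to_datetime(df[col])
    return df


def config_hash(config) -> str:
    """Stable short hash of any JSON-serialisable configuration object."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_outputs(
    results: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    metadata: Mapping | None = None,
) -> list[str]:
    """Write result tables plus a run-metadata file; return the file manifest.

    ``results`` maps table names (without extension) to DataFrames.  The
    metadata file records at least the seed, configuration hash and package
    version when provided by the caller.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    for name, df in results.items():
        path = out_dir / f"{name}.tsv"
        write_table(df, path)
        manifest.append(path.name)
    meta = dict(metadata or {})
    from . import __version__

    meta.setdefault("version", __version__)
    meta["files"] = sorted(manifest)
    meta_path = out_dir / "run_metadata.json"
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
    manifest.append(meta_path.name)
    return sorted(manifest)
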