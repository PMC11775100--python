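"""Quality control of raw eMR serum creatinine values.

Routine-care creatinine extracted from primary-care records contains
duplicated rows, implausible extremes and values below assay limits.  QC
assigns every raw record exactly one final status:

* values above the configured maximum (default 6524 µmol/L, the highest
  plausible recorded value) are excluded;
* values below the limit of detection (LOD) are excluded;
* exact duplicates (same person, date and value by default) keep the first
  occurrence in stable input order;
* values below the limit of quantification (LoQ) are floored to the LoQ and
  retained;
* everything else passes.

Study-center values bypass QC entirely: they were measured centrally with a
single standardized assay and serve as the gold standard.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .records_io import QcStatus

__all__ = ["QcConfig", "qc_emr_creatinine"]


@dataclass(frozen=True)
class QcConfig:
    """Thresholds for eMR creatinine QC.

    ``lod`` and ``loq`` are laboratory-specific placeholders (µmol/L); values
    strictly below ``lod`` are excluded, values in ``[lod, loq)`` are floored.
    ``duplicate_key`` defines what counts as a duplicate row; same-day records
    with differing values are kept as plausibly distinct draws.
    """

    lod: float = 18.0
    loq: float = 18.0
    max_value: float = 6524.0
    duplicate_key: tuple[str, ...] = ("person_id", "exam_date", "value")

    def __post_init__(self) -> None:
        if not (0 < self.lod <= self.loq < self.max_value):
            raise ValueError(
                f"require 0 < lod <= loq < max_value, got "
                f"lod={self.lod}, loq={self.loq}, max_value={self.max_value}"
            )


def qc_emr_creatinine(
    records: pd.DataFrame, config: QcConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run QC on eMR creatinine records.

    Parameters
    ----------
    records
        Creatinine records as produced by :mod:`egfrtraj.records_io`, with a
        ``qc_status`` column.  Rows already excluded upstream (technical
        errors) are passed through unchanged but counted in the report.
    config
        Thresholds; defaults to :class:`QcConfig`.

    Returns
    -------
    (passed, report)
        ``passed`` contains the records with final status ``pass`` or
        ``floored_to_loq``; ``report`` is a status -> count table over all
        input rows.

    Notes
    -----
    The operation is idempotent: re-running it on its own output changes
    nothing, because floored records (value already at the LoQ) retain their
    ``floored_to_loq`` status.  Duplicates are identified on the values as
    given, before flooring.
    """
    config = config or QcConfig()
    df = records.copy()
    checkable = df["qc_status"].isin([QcStatus.RAW, *QcStatus.KEPT])
    was_floored = df["qc_status"] == QcStatus.FLOORED_TO_LOQ

    status = df["qc_status"].copy()
    value = df["value"].copy()

    above = checkable & (value > config.max_value)
    status[above] = QcStatus.EXCLUDED_ABOVE_MAX
    below = checkable & ~above & (value < config.lod)
    status[below] = QcStatus.EXCLUDED_BELOW_LOD

    surviving = checkable & ~above & ~below
    dup = pd.Series(False, index=df.index)
    dup.loc[surviving] = (
        df.loc[surviving].duplicated(subset=list(config.duplicate_key), keep="first").to_numpy()
    )
    status[dup] = QcStatus.EXCLUDED_DUPLICATE

    kept = surviving & ~dup
    floor = kept & (value < config.loq)
    value[floor] = config.loq
    status[kept] = QcStatus.PASS
    status[kept & (floor | was_floored)] = QcStatus.FLOORED_TO_LOQ

    df["qc_status"] = status
    df["value"] = value

    counts = df["qc_status"].value_counts()
    report = pd.DataFrame(
        {"qc_status": list(QcStatus.ALL), "count": [int(counts.get(s, 0)) for s in QcStatus.ALL]}
    )
    report = report[report["qc_status"] != QcStatus.RAW].reset_index(drop=True)
    passed = df[df["qc_status"].isin(QcStatus.KEPT)].copy()
    return passed, report
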