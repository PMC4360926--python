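"""Patient records and cohorts: the data model plus CSV reading and writing.

A cohort is an ordered collection of single-admission records.  Only the
first set of vital signs measured on the day of admission is represented;
longitudinal measurements are out of scope.  The CSV column dictionary is
fixed (see :data:`COLUMNS`); booleans are encoded 0/1 and empty cells mean
missing, which is permitted only for the optional fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "COLUMNS",
    "REQUIRED_COLUMNS",
    "PatientRecord",
    "Cohort",
    "DropReport",
    "CohortFormatError",
    "RecordValidationError",
    "read_cohort",
    "write_cohort",
    "cohort_from_frame",
]

#: Canonical column order of the CSV interface.
COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "sbp",
    "dbp",
    "pulse",
    "resp_rate",
    "temperature",
    "gcs",
    "wbc",
    "platelets",
    "band_forms_pct",
    "suspected_infection",
    "died_in_hospital",
]

#: Fields that must be present and parseable in every record.
REQUIRED_COLUMNS = [
    "patient_id",
    "sbp",
    "dbp",
    "pulse",
    "resp_rate",
    "temperature",
    "gcs",
    "suspected_infection",
    "died_in_hospital",
]

OPTIONAL_COLUMNS = [c for c in COLUMNS if c not in REQUIRED_COLUMNS]


class CohortFormatError(ValueError):
    """The file does not conform to the cohort CSV contract."""


class RecordValidationError(ValueError):
    """A record violates a clinical-range invariant."""


class PatientRecord(BaseModel):
    """One admission: vitals, mental state, demographics and outcome.

    Pressures are mmHg, pulse beats/minute, respiratory rate cycles/minute,
    temperature axillary degrees Celsius at 0.1 resolution, white cells and
    platelets in thousands of cells per cc, band forms as a percentage.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    patient_id: str
    age: Optional[int] = Field(default=None, ge=0)
    sex: Optional[Literal["male", "female"]] = None
    sbp: float = Field(gt=0)
    dbp: float = Field(gt=0)
    pulse: float = Field(gt=0)
    resp_rate: float = Field(gt=0)
    temperature: float = Field(ge=25, le=45)
    gcs: int = Field(ge=3, le=15)
    wbc: Optional[float] = Field(default=None, ge=0)
    platelets: Optional[float] = Field(default=None, ge=0)
    band_forms_pct: Optional[float] = Field(default=None, ge=0)
    suspected_infection: bool
    died_in_hospital: bool

    @model_validator(mode="after")
    def _dbp_not_above_sbp(self) -> "PatientRecord":
        if self.dbp > self.sbp:
            raise ValueError(
                f"dbp ({self.dbp}) exceeds sbp ({self.sbp}) for patient "
                f"{self.patient_id!r}"
            )
        return self


@dataclass
class DropReport:
    """Summary of records rejected by lenient reading."""

    n_read: int = 0
    n_dropped: int = 0
    reasons: list[str] = field(default_factory=list)


@dataclass
class Cohort:
    """An ordered, uniquely-identified collection of patient records."""

    label: str
    records: list[PatientRecord]

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise RecordValidationError(
                f"duplicate patient_id values in cohort {self.label!r}: {dupes}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with the canonical column order."""
        rows = []
        for r in self.records:
            d = r.model_dump()
            d["sex"] = d["sex"] if d["sex"] is not None else None
            d["suspected_infection"] = int(d["suspected_infection"])
            d["died_in_hospital"] = int(d["died_in_hospital"])
            rows.append(d)
        return pd.DataFrame(rows, columns=COLUMNS)

    @property
    def outcomes(self) -> list[bool]:
        return [r.died_in_hospital for r in self.records]


def _parse_bool(value, column: str, row: int) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)) and not (
        isinstance(value, float) and math.isnan(value)
    ):
        if value in (0, 1):
            return bool(value)
    if isinstance(value, str) and value.strip().lower() in {
        "0", "1", "true", "false",
    }:
        return value.strip().lower() in {"1", "true"}
    raise CohortFormatError(
        f"row {row}: column {column!r} must be 0/1, got {value!r}"
    )


def _row_to_record(row: pd.Series, row_number: int) -> PatientRecord:
    data: dict = {}
    for col in COLUMNS:
        raw = row.get(col)
        missing = raw is None or (isinstance(raw, float) and math.isnan(raw)) or (
            isinstance(raw, str) and raw.strip() == ""
        )
        if missing:
            if col in REQUIRED_COLUMNS:
                raise RecordValidationError(
                    f"row {row_number}: required field {col!r} is missing"
                )
            data[col] = None
            continue
        if col in ("suspected_infection", "died_in_hospital"):
            data[col] = _parse_bool(raw, col, row_number)
        elif col in ("patient_id", "sex"):
            data[col] = str(raw).strip()
        elif col in ("gcs", "age"):
            try:
                data[col] = int(float(raw))
            except (TypeError, ValueError):
                raise CohortFormatError(
                    f"row {row_number}: cannot parse {col!r} value {raw!r}"
                ) from None
        else:
            try:
                data[col] = float(raw)
            except (TypeError, ValueError):
                raise CohortFormatError(
                    f"row {row_number}: cannot parse {col!r} value {raw!r}"
                ) from None
    try:
        return PatientRecord(**data)
    except (ValueError, TypeError) as exc:
        raise RecordValidationError(f"row {row_number}: {exc}") from None


def cohort_from_frame(
    frame: pd.DataFrame,
    label: str = "cohort",
    strict: bool = True,
) -> tuple[Cohort, DropReport]:
    """Build a validated cohort from a data frame.

    With ``strict`` the first invalid record aborts; otherwise invalid
    records are dropped and counted in the returned report.
    """
    cols = {c.lower().strip(): c for c in frame.columns}
    missing = [c for c in REQUIRED_COLUMNS if c not in cols]
    if missing:
        raise CohortFormatError(f"missing required column(s): {missing}")
    frame = frame.rename(columns={v: k for k, v in cols.items()})

    report = DropReport(n_read=len(frame))
    records: list[PatientRecord] = []
    for i, (_, row) in enumerate(frame.iterrows()):
        row_number = i + 2  # 1-based with header line
        try:
            records.append(_row_to_record(row, row_number))
        except (RecordValidationError, CohortFormatError) as exc:
            if strict:
                raise
            report.n_dropped += 1
            report.reasons.append(str(exc))
    return Cohort(label=label, records=records), report


def read_cohort(
    path: str | Path,
    strict: bool = True,
    label: str | None = None,
) -> tuple[Cohort, DropReport]:
    """Read a cohort CSV (UTF-8, header row required).

    Returns the cohort together with a report of any records dropped under
    lenient (``strict=False``) reading.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype={"patient_id": str, "sex": str})
    return cohort_from_frame(frame, label=label or path.stem, strict=strict)


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort to CSV such that reading it back is the identity."""
    path = Path(path)
    frame = cohort.to_frame()
    frame.to_csv(path, index=False)
    return path
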