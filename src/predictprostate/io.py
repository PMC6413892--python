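"""Cohort file reading, validation and exclusion filtering.

Cohorts are flat comma-separated tables (UTF-8, dot decimal) with the
documented column schema; missing values are empty strings or "NA".  Rows
failing type coercion or bounds checks are collected into an error report
rather than silently dropped; records with missing key predictors survive
reading and are removed — with machine-readable reasons — by
:func:`apply_exclusions`, mirroring a complete-case registry analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import PatientRecord, TREATMENT_LEVELS

__all__ = [
    "SchemaError",
    "EmptyCohortError",
    "CohortReadResult",
    "read_cohort",
    "apply_exclusions",
    "records_to_frame",
    "frame_to_records",
    "COLUMNS",
]

# canonical column order of a cohort CSV; event coding 0=censored,
# 1=PCa death, 2=other death
COLUMNS = (
    "id",
    "age",
    "psa",
    "grade_group",
    "t_stage",
    "treatment",
    "comorbidity",
    "cores_positive",
    "cores_total",
    "time_years",
    "event",
)

REQUIRED = ("id", "age", "psa", "grade_group", "t_stage", "treatment")

_NA = {"", "NA", "na", "NaN", "nan", None}


class SchemaError(ValueError):
    """A required column is absent from the cohort file."""


class EmptyCohortError(ValueError):
    """The cohort file contains no data rows."""


@dataclass
class RowError:
    row: int
    column: str
    message: str


@dataclass
class CohortReadResult:
    records: list[PatientRecord]
    errors: list[RowError] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


def _opt_float(value, *, positive=False):
    if value in _NA or (isinstance(value, float) and math.isnan(value)):
        return None
    v = float(value)
    if positive and v <= 0:
        raise ValueError("must be positive")
    return v


def _opt_int(value, lo=None, hi=None):
    if value in _NA or (isinstance(value, float) and math.isnan(value)):
        return None
    v = float(value)
    if v != int(v):
        raise ValueError("must be an integer")
    v = int(v)
    if (lo is not None and v < lo) or (hi is not None and v > hi):
        raise ValueError(f"out of bounds [{lo}, {hi}]")
    return v


def _parse_row(i: int, row: Mapping, errors: list[RowError]) -> PatientRecord | None:
    ok = True

    def grab(col, parser, **kw):
        nonlocal ok
        try:
            return parser(row.get(col), **kw)
        except (TypeError, ValueError) as exc:
            errors.append(RowError(i, col, str(exc) or "type coercion failed"))
            ok = False
            return None

    age = grab("age", _opt_float)
    psa = grab("psa", _opt_float, positive=True)
    grade = grab("grade_group", _opt_int, lo=1, hi=5)
    t_stage = grab("t_stage", _opt_int, lo=1, hi=4)
    treatment = row.get("treatment")
    if treatment in _NA:
        treatment = None
    elif treatment not in TREATMENT_LEVELS:
        errors.append(
            RowError(i, "treatment", f"unknown level {treatment!r}")
        )
        ok = False
    comorbidity = grab("comorbidity", _opt_int, lo=0, hi=1)
    cores_positive = grab("cores_positive", _opt_int, lo=0)
    cores_total = grab("cores_total", _opt_int, lo=1)
    if (
        cores_positive is not None
        and cores_total is not None
        and cores_positive > cores_total
    ):
        errors.append(
            RowError(i, "cores_positive", "cores_positive exceeds cores_total")
        )
        ok = False
    time = grab("time_years", _opt_float)
    if time is not None and time < 0:
        errors.append(RowError(i, "time_years", "negative follow-up time"))
        ok = False
    event = grab("event", _opt_int, lo=0, hi=2)
    if not ok:
        return None
    return PatientRecord(
        id=str(row.get("id", i)),
        age=age,
        psa=psa,
        grade_group=grade,
        t_stage=t_stage,
        treatment=treatment,
        comorbidity=comorbidity,
        cores_positive=cores_positive,
        cores_total=cores_total,
        time=time,
        event=event,
    )


def read_cohort(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> CohortReadResult:
    """Read a cohort CSV into typed records plus a row-level error report.

    ``schema`` optionally maps canonical column names to the file's column
    names.  Missing required columns raise :class:`SchemaError`; an empty
    file raises :class:`EmptyCohortError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise EmptyCohortError(f"cohort file {path} contains no data rows")
    errors: list[RowError] = []
    records = []
    for i, row in enumerate(df.to_dict(orient="records")):
        rec = _parse_row(i, row, errors)
        if rec is not None:
            records.append(rec)
    return CohortReadResult(records=records, errors=errors)


# exclusion reason codes, applied in this order per record
_EXCLUSION_CHECKS = (
    ("missing_age", lambda r: r.age is None),
    ("missing_psa", lambda r: r.psa is None),
    ("missing_grade_group", lambda r: r.grade_group is None),
    ("missing_t_stage", lambda r: r.t_stage is None),
    ("missing_treatment", lambda r: r.treatment is None),
    ("psa_ge_100", lambda r: r.psa is not None and r.psa >= 100.0),
)


def apply_exclusions(
    records: Sequence[PatientRecord],
) -> tuple[list[PatientRecord], list[tuple[PatientRecord, str]]]:
    """Complete-case and PSA exclusion filter.

    Removes records with PSA >= 100 ng/mL (surrogate for occult metastatic
    disease) and records missing any key predictor; each exclusion carries a
    machine-readable reason code.  Idempotent.  Nodal/metastatic exclusion
    happens upstream of this package's data and is not re-checked here.
    """
    kept: list[PatientRecord] = []
    excluded: list[tuple[PatientRecord, str]] = []
    for rec in records:
        for reason, check in _EXCLUSION_CHECKS:
            if check(rec):
                excluded.append((rec, reason))
                break
        else:
            kept.append(rec)
    return kept, excluded


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Records to the canonical cohort DataFrame (NaN for missing)."""
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "age": np.nan if r.age is None else r.age,
                "psa": np.nan if r.psa is None else r.psa,
                "grade_group": np.nan if r.grade_group is None else r.grade_group,
                "t_stage": np.nan if r.t_stage is None else r.t_stage,
                "treatment": r.treatment,
                "comorbidity": np.nan if r.comorbidity is None else r.comorbidity,
                "cores_positive": np.nan
                if r.cores_positive is None
                else r.cores_positive,
                "cores_total": np.nan if r.cores_total is None else r.cores_total,
                "time_years": np.nan if r.time is None else r.time,
                "event": np.nan if r.event is None else r.event,
            }
        )
    return pd.DataFrame(rows, columns=COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    """Canonical cohort DataFrame to typed records."""

    def opt(v, cast=float):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return cast(v)

    out = []
    for i, row in df.iterrows():
        out.append(
            PatientRecord(
                id=str(row["id"]),
                age=opt(row["age"]),
                psa=opt(row["psa"]),
                grade_group=opt(row["grade_group"], int),
                t_stage=opt(row["t_stage"], int),
                treatment=None if pd.isna(row["treatment"]) else str(row["treatment"]),
                comorbidity=opt(row.get("comorbidity"), int),
                cores_positive=opt(row.get("cores_positive"), int),
                cores_total=opt(row.get("cores_total"), int),
                time=opt(row.get("time_years")),
                event=opt(row.get("event"), int),
            )
        )
    return out
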