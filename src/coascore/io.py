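"""Cohort CSV schema, parsing, and serialisation.

One row per fetus.  Header names are exact and case-sensitive; booleans
serialise as 0/1; missing values are empty cells; gestational age is
accepted as decimal weeks or as a "weeks+days" string ("24+3").  Required
columns: record_id, ga_weeks, aao_z (or aao_mm), isthmus_3vt_z (or
isthmus_3vt_mm), pv_mm, av_mm.  Everything else is optional.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, fields
from typing import Iterable, Sequence

import pandas as pd

from .score import ArchFlow, FetalEchoExam, ForamenOvaleFlow
from .validation import CohortRecord

__all__ = [
    "CohortRow",
    "RowError",
    "SchemaError",
    "COHORT_COLUMNS",
    "REQUIRED_COLUMNS",
    "parse_ga",
    "read_cohort",
    "write_cohort",
    "records_to_frame",
]


class SchemaError(ValueError):
    """The CSV lacks a required column."""


@dataclass(frozen=True)
class RowError:
    line: int  # 1-based file line (header is line 1)
    record_id: str
    message: str


@dataclass(frozen=True)
class CohortRow:
    """A parsed cohort row: exam plus outcome and eligibility flags."""

    record_id: str
    exam: FetalEchoExam
    outcome_coao: bool | None = None
    chromosomal_abnormality: bool = False
    growth_restriction: bool = False
    associated_major_chd: bool = False
    extrinsic_compression: bool = False
    lost_follow_up: bool = False


_FLOAT_EXAM_FIELDS = (
    "aao_z",
    "isthmus_3vt_z",
    "pv_mm",
    "av_mm",
    "aao_mm",
    "isthmus_3vt_mm",
    "isthmus_sagittal_mm",
    "tv_mm",
    "mv_mm",
    "mpa_mm",
    "da_3vt_mm",
    "rv_mm",
    "lv_mm",
    "mv_z",
    "tv_z",
    "transverse_arch_z",
    "isthmus_ductal_angle_deg",
    "csa_index",
    "transaortic_peak_velocity",
)
_BOOL_EXAM_FIELDS = (
    "plsvc",
    "rfop",
    "diffuse_arch_hypoplasia",
    "contraductal_shelf",
    "vsd",
    "aoisth_diastolic_flow_persistence",
)
_FLAG_FIELDS = (
    "chromosomal_abnormality",
    "growth_restriction",
    "associated_major_chd",
    "extrinsic_compression",
    "lost_follow_up",
)

COHORT_COLUMNS: tuple[str, ...] = (
    ("record_id", "ga_weeks")
    + _FLOAT_EXAM_FIELDS
    + _BOOL_EXAM_FIELDS
    + ("arch_flow", "fo_flow", "outcome_coao")
    + _FLAG_FIELDS
)

REQUIRED_COLUMNS: tuple[str, ...] = ("record_id", "ga_weeks", "pv_mm", "av_mm")
_EITHER_COLUMNS: tuple[tuple[str, str], ...] = (
    ("aao_z", "aao_mm"),
    ("isthmus_3vt_z", "isthmus_3vt_mm"),
)


def parse_ga(text: str | float) -> float:
    """Decimal gestational weeks from a number or a 'weeks+days' string."""
    if isinstance(text, (int, float)):
        return float(text)
    text = text.strip()
    if "+" in text:
        weeks, days = text.split("+", 1)
        return float(weeks) + float(days) / 7.0
    return float(text)


def _parse_bool(cell: str, column: str) -> bool:
    cell = cell.strip().lower()
    if cell in ("1", "true"):
        return True
    if cell in ("0", "false"):
        return False
    raise ValueError(f"column {column!r}: expected 0/1, got {cell!r}")


def read_cohort(path) -> tuple[list[CohortRow], list[RowError]]:
    """Parse a cohort CSV into typed rows, collecting per-row errors.

    Raises :class:`SchemaError` when a required column is absent; rows
    failing validation (e.g. a non-positive diameter) are reported in the
    second return value with their file line number while the remaining
    rows load normally.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    columns = set(frame.columns)
    for col in REQUIRED_COLUMNS:
        if col not in columns:
            raise SchemaError(f"required column {col!r} is missing")
    for z_col, mm_col in _EITHER_COLUMNS:
        if z_col not in columns and mm_col not in columns:
            raise SchemaError(f"either {z_col!r} or {mm_col!r} must be present")

    rows: list[CohortRow] = []
    errors: list[RowError] = []
    for idx, raw in enumerate(frame.to_dict(orient="records")):
        line = idx + 2  # header occupies line 1
        record_id = str(raw.get("record_id", "")).strip()
        try:
            kwargs: dict = {"ga_weeks": parse_ga(raw["ga_weeks"])}
            for col in _FLOAT_EXAM_FIELDS:
                cell = str(raw.get(col, "")).strip()
                if cell:
                    kwargs[col] = float(cell)
            for col in _BOOL_EXAM_FIELDS:
                cell = str(raw.get(col, "")).strip()
                if cell:
                    kwargs[col] = _parse_bool(cell, col)
            cell = str(raw.get("arch_flow", "")).strip()
            if cell:
                kwargs["arch_flow"] = ArchFlow(cell)
            cell = str(raw.get("fo_flow", "")).strip()
            if cell:
                kwargs["fo_flow"] = ForamenOvaleFlow(cell)
            exam = FetalEchoExam(**kwargs)
            outcome_cell = str(raw.get("outcome_coao", "")).strip()
            outcome = _parse_bool(outcome_cell, "outcome_coao") if outcome_cell else None
            flags = {}
            for col in _FLAG_FIELDS:
                cell = str(raw.get(col, "")).strip()
                flags[col] = _parse_bool(cell, col) if cell else False
            rows.append(
                CohortRow(record_id=record_id, exam=exam, outcome_coao=outcome, **flags)
            )
        except (ValueError, KeyError) as exc:
            errors.append(RowError(line=line, record_id=record_id, message=str(exc)))
    return rows, errors


def _format(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, (ArchFlow, ForamenOvaleFlow)):
        return value.value
    if isinstance(value, float):
        return repr(value)  # shortest round-trip representation
    return str(value)


def _row_cells(row, extra: dict | None = None) -> dict[str, str]:
    exam = row.exam
    cells = {"record_id": row.record_id, "ga_weeks": _format(exam.ga_weeks)}
    for col in _FLOAT_EXAM_FIELDS + _BOOL_EXAM_FIELDS + ("arch_flow", "fo_flow"):
        cells[col] = _format(getattr(exam, col))
    cells["outcome_coao"] = _format(getattr(row, "outcome_coao", None))
    for col in _FLAG_FIELDS:
        cells[col] = _format(getattr(row, col, False))
    if extra:
        cells.update({k: _format(v) for k, v in extra.items()})
    return cells


def write_cohort(
    rows: Sequence, path, *, include_prediction: bool = False
) -> None:
    """Write cohort rows or records to CSV in the canonical column order.

    With ``include_prediction``, a predicted_probability column (6 decimal
    places) and its display percent are appended — used for scored
    cohorts (:class:`~coascore.validation.CohortRecord` inputs).
    """
    columns = list(COHORT_COLUMNS)
    if include_prediction:
        columns += ["predicted_probability", "predicted_percent"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns)
        writer.writeheader()
        for row in rows:
            extra = None
            if include_prediction:
                p = row.predicted_probability
                extra = {
                    "predicted_probability": f"{p:.6f}",
                    "predicted_percent": str(round(100.0 * p)),
                }
            writer.writerow(_row_cells(row, extra))


def records_to_frame(records: Iterable[CohortRecord]) -> pd.DataFrame:
    """Scored records as a DataFrame (one row per fetus)."""
    rows = []
    for r in records:
        cells = _row_cells(r)
        cells["predicted_probability"] = r.predicted_probability
        cells["onset_group"] = r.onset_group
        rows.append(cells)
    return pd.DataFrame(rows)
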