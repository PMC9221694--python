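"""Cohort table I/O.

The shared on-disk format is a UTF-8 comma-separated table with one row per
subject.  Floats are written with Python's shortest round-trip representation
so write → read → write is byte-identical.  A cohort table may alternatively
carry qPCR threshold cycles (``<MARKER>_ct`` columns plus ``normalizer_ct``
and ``reference_dct``); these are converted to relative expression with the
ΔΔCT method on read, flagging cycles at/above the detection cutoff.
"""

from __future__ import annotations

import csv
import io as _io
import warnings
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

from .cohort import (
    CL,
    MAP,
    Outcome,
    RNA_MARKERS,
    RawMeasurement,
    SubjectRecord,
)
from .expression import DEFAULT_MAX_CT, CtRecord, flag_below_detection

COLUMNS: List[str] = [
    "subject_id",
    "ga_sampling_days",
    "weight_kg",
    "race_nhb",
    "smoker",
    "parity",
    "prior_ptb",
    "earliest_prior_ptb_weeks",
    "outcome",
    *RNA_MARKERS,
    CL,
    MAP,
    *[f"{m}_below_detection" for m in RNA_MARKERS],
]

_CT_COLUMNS: List[str] = [
    "subject_id",
    "ga_sampling_days",
    "weight_kg",
    "race_nhb",
    "smoker",
    "parity",
    "prior_ptb",
    "earliest_prior_ptb_weeks",
    "outcome",
    *[f"{m}_ct" for m in RNA_MARKERS],
    "normalizer_ct",
    "reference_dct",
    CL,
    MAP,
]


class CohortIOError(ValueError):
    """Malformed cohort table (message names the offending row)."""


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def cohort_to_table(cohort: Sequence[SubjectRecord]) -> str:
    """Render a cohort as CSV text (header + one row per subject)."""
    if not cohort:
        raise ValueError("empty cohort")
    buf = _io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(COLUMNS)
    for s in cohort:
        row = [
            s.subject_id,
            s.ga_sampling_days,
            _fmt(s.maternal_weight_kg),
            _fmt(s.race_nhb),
            _fmt(s.smoker),
            s.parity,
            _fmt(s.prior_ptb),
            _fmt(s.earliest_prior_ptb_weeks),
            s.outcome.value,
        ]
        for m in RNA_MARKERS:
            row.append(_fmt(s.markers[m].value if m in s.markers else None))
        row.append(_fmt(s.cl_cm))
        row.append(_fmt(s.map_mmhg))
        for m in RNA_MARKERS:
            flagged = m in s.markers and s.markers[m].below_detection
            row.append(_fmt(bool(flagged)))
        writer.writerow(row)
    return buf.getvalue()


def write_cohort(cohort: Sequence[SubjectRecord], path: Union[str, Path]) -> None:
    Path(path).write_text(cohort_to_table(cohort), encoding="utf-8")


def _parse_bool(text: str, row: int, col: str) -> bool:
    if text in ("true", "True", "1"):
        return True
    if text in ("false", "False", "0"):
        return False
    raise CohortIOError(f"row {row}: column {col!r} has non-boolean value {text!r}")


def _parse_float(text: str, row: int, col: str) -> Optional[float]:
    if text == "":
        return None
    try:
        return float(text)
    except ValueError:
        raise CohortIOError(f"row {row}: column {col!r} has non-numeric value {text!r}")


def _require(text: str, row: int, col: str) -> str:
    if text == "":
        raise CohortIOError(f"row {row}: required column {col!r} is empty")
    return text


def read_cohort(path: Union[str, Path], max_ct: float = DEFAULT_MAX_CT) -> List[SubjectRecord]:
    """Parse a cohort table into typed records.

    Accepts the expression schema or the CT-mode schema (detected from the
    header).  Malformed rows raise :class:`CohortIOError` naming the row;
    duplicate subject ids are rejected; an empty data section returns an
    empty cohort with a warning.
    """
    text = Path(path).read_text(encoding="utf-8")
    reader = csv.reader(_io.StringIO(text))
    try:
        header = next(reader)
    except StopIteration:
        raise CohortIOError("file has no header row")

    ct_mode = any(f"{m}_ct" in header for m in RNA_MARKERS)
    expected = _CT_COLUMNS if ct_mode else COLUMNS
    if header != expected:
        raise CohortIOError(
            f"header mismatch: expected {expected}, got {header}"
        )

    records: List[SubjectRecord] = []
    seen: set = set()
    for rownum, row in enumerate(reader, start=2):
        if not row:
            continue
        if len(row) != len(expected):
            raise CohortIOError(
                f"row {rownum}: {len(row)} fields, expected {len(expected)}"
            )
        f = dict(zip(expected, row))
        sid = _require(f["subject_id"], rownum, "subject_id")
        if sid in seen:
            raise CohortIOError(f"row {rownum}: duplicate subject_id {sid!r}")
        seen.add(sid)
        try:
            outcome = Outcome(f["outcome"])
        except ValueError:
            raise CohortIOError(
                f"row {rownum}: unknown outcome {f['outcome']!r}"
            )
        try:
            ga = int(_require(f["ga_sampling_days"], rownum, "ga_sampling_days"))
        except ValueError:
            raise CohortIOError(
                f"row {rownum}: non-integer ga_sampling_days {f['ga_sampling_days']!r}"
            )

        markers: Dict[str, RawMeasurement] = {}
        if ct_mode:
            norm_ct = _parse_float(f["normalizer_ct"], rownum, "normalizer_ct")
            ref_dct = _parse_float(f["reference_dct"], rownum, "reference_dct")
            ct_records = [
                CtRecord(_parse_float(f[f"{m}_ct"], rownum, f"{m}_ct"), norm_ct, ref_dct)
                for m in RNA_MARKERS
            ]
            for m, meas in zip(RNA_MARKERS, flag_below_detection(ct_records, max_ct)):
                markers[m] = meas
        else:
            for m in RNA_MARKERS:
                below = _parse_bool(
                    f[f"{m}_below_detection"] or "false", rownum, f"{m}_below_detection"
                )
                value = _parse_float(f[m], rownum, m)
                markers[m] = RawMeasurement(None if below else value, below)

        try:
            rec = SubjectRecord(
                subject_id=sid,
                ga_sampling_days=ga,
                maternal_weight_kg=_parse_float(
                    _require(f["weight_kg"], rownum, "weight_kg"), rownum, "weight_kg"
                ),
                race_nhb=_parse_bool(f["race_nhb"], rownum, "race_nhb"),
                smoker=_parse_bool(f["smoker"], rownum, "smoker"),
                parity=int(_require(f["parity"], rownum, "parity")),
                prior_ptb=_parse_bool(f["prior_ptb"], rownum, "prior_ptb"),
                earliest_prior_ptb_weeks=_parse_float(
                    _require(f["earliest_prior_ptb_weeks"], rownum,
                             "earliest_prior_ptb_weeks"),
                    rownum, "earliest_prior_ptb_weeks",
                ),
                outcome=outcome,
                markers=markers,
                cl_cm=_parse_float(f[CL], rownum, CL),
                map_mmhg=_parse_float(f[MAP], rownum, MAP),
            )
        except ValueError as exc:
            raise CohortIOError(f"row {rownum}: {exc}") from exc
        records.append(rec)

    if not records:
        warnings.warn(f"{path}: no data rows; empty cohort")
    return records
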