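"""CSV schemas and typed readers/writers.

Two interchange formats, both plain UTF-8 CSV with a header row:

* plate CSV — one row per well: ``plate_id, sample_id, condition, signal,
  coverage_mm2, replicate_index``; condition labels are the blocking-condition
  enumeration, matched case-insensitively; unknown columns are preserved on
  the record's ``extra`` dict.
* cohort CSV — one row per patient: ``patient_id, best_response, os_months,
  os_event, pfs_months, pfs_event, line_of_treatment, cps_value, pd1_score,
  pdl1_score, pdl2_score, response_start_months, response_end_months,
  ongoing``; booleans accept 0/1/true/false, optional fields may be blank.

Errors name the offending column or carry the 1-based data row number so
problems in hand-edited tables are findable.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .cohort import PatientRecord
from .errors import IcarError
from .scoring import BlockingCondition, LigandScoreSet, WellRecord

__all__ = [
    "PLATE_COLUMNS",
    "COHORT_COLUMNS",
    "read_plate_csv",
    "write_plate_csv",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_cps_counts_csv",
    "write_scores_csv",
]

PLATE_COLUMNS = ("plate_id", "sample_id", "condition", "signal", "coverage_mm2", "replicate_index")
COHORT_COLUMNS = (
    "patient_id",
    "best_response",
    "os_months",
    "os_event",
    "pfs_months",
    "pfs_event",
    "line_of_treatment",
    "cps_value",
    "pd1_score",
    "pdl1_score",
    "pdl2_score",
    "response_start_months",
    "response_end_months",
    "ongoing",
)
CPS_COUNT_COLUMNS = (
    "sample_id",
    "pdl1_positive_tumor_cells",
    "pdl1_positive_immune_cells",
    "total_viable_tumor_cells",
)

_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no"}


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise IcarError("missing_column", f"{path}: missing required column(s) {', '.join(missing)}")


def _is_blank(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or str(value).strip() == ""


def _as_float(value, column, row, *, optional=False) -> float | None:
    if _is_blank(value):
        if optional:
            return None
        raise IcarError("missing_value", f"row {row}: column {column} is blank")
    try:
        return float(value)
    except (TypeError, ValueError):
        raise IcarError("non_numeric", f"row {row}: column {column} value {value!r} is not numeric")


def _as_int(value, column, row) -> int:
    f = _as_float(value, column, row)
    if f != int(f):
        raise IcarError("non_numeric", f"row {row}: column {column} value {value!r} is not an integer")
    return int(f)


def _as_bool(value, column, row) -> bool:
    if _is_blank(value):
        raise IcarError("missing_value", f"row {row}: column {column} is blank")
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise IcarError("invalid_boolean", f"row {row}: column {column} value {value!r} is not a boolean")


def read_plate_csv(path) -> list[WellRecord]:
    """Read a plate CSV into typed well records (row numbers in errors)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, PLATE_COLUMNS, path)
    extra_cols = [c for c in df.columns if c not in PLATE_COLUMNS]
    wells = []
    for i, rec in enumerate(df.to_dict("records")):
        row = i + 1
        condition = BlockingCondition.parse(rec["condition"])
        needs_cov = condition not in (BlockingCondition.POSITIVE_CONTROL, BlockingCondition.BLANK)
        wells.append(
            WellRecord(
                plate_id=str(rec["plate_id"]),
                sample_id=str(rec["sample_id"]),
                condition=condition,
                signal=_as_float(rec["signal"], "signal", row),
                coverage_mm2=_as_float(rec["coverage_mm2"], "coverage_mm2", row, optional=not needs_cov),
                replicate_index=_as_int(rec["replicate_index"], "replicate_index", row),
                extra={c: rec[c] for c in extra_cols},
            )
        )
    return wells


def write_plate_csv(wells: list[WellRecord], path) -> None:
    rows = [
        {
            "plate_id": w.plate_id,
            "sample_id": w.sample_id,
            "condition": w.condition.value,
            "signal": w.signal,
            "coverage_mm2": w.coverage_mm2,
            "replicate_index": w.replicate_index,
        }
        for w in wells
    ]
    pd.DataFrame(rows, columns=list(PLATE_COLUMNS)).to_csv(path, index=False)


def read_cohort_csv(path) -> list[PatientRecord]:
    """Read a cohort CSV into typed patient records."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, COHORT_COLUMNS, path)
    patients = []
    for i, rec in enumerate(df.to_dict("records")):
        row = i + 1
        scores = LigandScoreSet(
            sample_id=str(rec["patient_id"]),
            pd1_score=_as_float(rec["pd1_score"], "pd1_score", row, optional=True),
            pdl1_score=_as_float(rec["pdl1_score"], "pdl1_score", row, optional=True),
            pdl2_score=_as_float(rec["pdl2_score"], "pdl2_score", row, optional=True),
        )
        patients.append(
            PatientRecord(
                patient_id=str(rec["patient_id"]),
                best_response=str(rec["best_response"]).strip().upper(),
                os_months=_as_float(rec["os_months"], "os_months", row),
                os_event=_as_bool(rec["os_event"], "os_event", row),
                pfs_months=_as_float(rec["pfs_months"], "pfs_months", row),
                pfs_event=_as_bool(rec["pfs_event"], "pfs_event", row),
                line_of_treatment=_as_int(rec["line_of_treatment"], "line_of_treatment", row),
                cps_value=_as_float(rec["cps_value"], "cps_value", row, optional=True),
                scores=scores,
                response_start_months=_as_float(
                    rec["response_start_months"], "response_start_months", row, optional=True
                ),
                response_end_months=_as_float(
                    rec["response_end_months"], "response_end_months", row, optional=True
                ),
                ongoing=_as_bool(rec["ongoing"], "ongoing", row) if not _is_blank(rec["ongoing"]) else False,
            )
        )
    return patients


def write_cohort_csv(patients: list[PatientRecord], path) -> None:
    rows = []
    for p in patients:
        rows.append(
            {
                "patient_id": p.patient_id,
                "best_response": p.best_response,
                "os_months": p.os_months,
                "os_event": int(p.os_event),
                "pfs_months": p.pfs_months,
                "pfs_event": int(p.pfs_event),
                "line_of_treatment": p.line_of_treatment,
                "cps_value": p.cps_value,
                "pd1_score": p.scores.pd1_score,
                "pdl1_score": p.scores.pdl1_score,
                "pdl2_score": p.scores.pdl2_score,
                "response_start_months": p.response_start_months,
                "response_end_months": p.response_end_months,
                "ongoing": int(p.ongoing),
            }
        )
    pd.DataFrame(rows, columns=list(COHORT_COLUMNS)).to_csv(path, index=False)


def read_cps_counts_csv(path) -> pd.DataFrame:
    """Raw PD-L1 staining counts (one row per sample) for CPS computation."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, CPS_COUNT_COLUMNS, path)
    return df


def write_scores_csv(score_sets, path) -> None:
    pd.DataFrame([s.as_dict() for s in score_sets]).to_csv(path, index=False)
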