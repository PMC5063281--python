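"""CSV/JSON interchange for visit-level cohorts.

`visits.csv` carries exactly the fields of a visit record; columns are
matched by name, so header order is free.  Absent TFT times are empty cells
and are legal only when the corresponding ability flag is false.
"""

from __future__ import annotations

import json
import math

import pandas as pd

from .cohort import GENOTYPE_CLASSES, TruthRecord, VisitRecord
from .errors import DataIntegrityError, SchemaError

__all__ = ["VISIT_COLUMNS", "read_visits", "write_visits", "write_truth"]

VISIT_COLUMNS = (
    "patient_id",
    "age",
    "date_offset",
    "height",
    "weight",
    "six_mwd",
    "tft_rise_time",
    "tft_rise_able",
    "tft_10mwr_time",
    "tft_10mwr_able",
    "tft_4sc_time",
    "tft_4sc_able",
    "steroid_duration",
    "genotype",
)

_FLOAT_COLUMNS = ("age", "height", "weight", "six_mwd", "steroid_duration")
_BOOL_TRUE = {"true", "1", "yes"}
_BOOL_FALSE = {"false", "0", "no"}


def write_visits(visits: list[VisitRecord], path) -> None:
    frame = pd.DataFrame([vars(v) for v in visits], columns=list(VISIT_COLUMNS))
    frame.to_csv(path, index=False)


def write_truth(truth: TruthRecord, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)


def _parse_bool(raw, row: int, column: str) -> bool:
    text = str(raw).strip().lower()
    if text in _BOOL_TRUE:
        return True
    if text in _BOOL_FALSE:
        return False
    raise SchemaError(f"row {row}: cannot parse {column}={raw!r} as a boolean")


def _parse_float(raw, row: int, column: str) -> float:
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise SchemaError(f"row {row}: cannot parse {column}={raw!r} as a number") from None
    if math.isnan(value):
        raise SchemaError(f"row {row}: column {column} is missing")
    return value


def read_visits(path) -> list[VisitRecord]:
    """Read a visit table, validating the schema and able/time consistency."""
    frame = pd.read_csv(path, dtype=str)
    unknown = set(frame.columns) - set(VISIT_COLUMNS)
    if unknown:
        raise SchemaError(f"unknown column(s) in visit table: {sorted(unknown)}")
    missing = set(VISIT_COLUMNS) - set(frame.columns)
    if missing:
        raise SchemaError(f"visit table lacks column(s): {sorted(missing)}")

    visits: list[VisitRecord] = []
    for i, rec in enumerate(frame.to_dict("records")):
        row = i + 2  # 1-based with header, for human-readable messages
        tft: dict[str, tuple[float | None, bool]] = {}
        for test in ("rise", "10mwr", "4sc"):
            able = _parse_bool(rec[f"tft_{test}_able"], row, f"tft_{test}_able")
            raw_time = rec[f"tft_{test}_time"]
            has_time = raw_time is not None and str(raw_time).strip() not in ("", "nan")
            if able and not has_time:
                raise DataIntegrityError(
                    f"row {row}: tft_{test}_able=true but tft_{test}_time is absent"
                )
            if not able and has_time:
                raise DataIntegrityError(
                    f"row {row}: tft_{test}_able=false but tft_{test}_time={raw_time!r}"
                )
            tft[test] = (_parse_float(raw_time, row, f"tft_{test}_time") if has_time else None, able)
        genotype = str(rec["genotype"]).strip()
        if genotype not in GENOTYPE_CLASSES:
            raise SchemaError(f"row {row}: unknown genotype {genotype!r}")
        visits.append(
            VisitRecord(
                patient_id=str(rec["patient_id"]).strip(),
                age=_parse_float(rec["age"], row, "age"),
                date_offset=int(_parse_float(rec["date_offset"], row, "date_offset")),
                height=_parse_float(rec["height"], row, "height"),
                weight=_parse_float(rec["weight"], row, "weight"),
                six_mwd=_parse_float(rec["six_mwd"], row, "six_mwd"),
                tft_rise_time=tft["rise"][0],
                tft_rise_able=tft["rise"][1],
                tft_10mwr_time=tft["10mwr"][0],
                tft_10mwr_able=tft["10mwr"][1],
                tft_4sc_time=tft["4sc"][0],
                tft_4sc_able=tft["4sc"][1],
                steroid_duration=_parse_float(rec["steroid_duration"], row, "steroid_duration"),
                genotype=genotype,
            )
        )
    return visits
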