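"""Reading and writing participant records, coefficients and results.

Records travel as UTF-8 CSV with a header row and reserved column
names (case-insensitive on read, canonical lower-case on write):
``id``, ``eurod_item_1`` .. ``eurod_item_12`` (optional),
``eurod_total`` (optional), ``recall``, ``cogscore``, ``relscore``,
``group``, ``site``, ``standard_class``.  An empty cell is a missing
value.  Either the item columns or ``eurod_total`` must be present.

The CSV dialect is fixed — comma separator, ``.`` decimal point, no
thousands separators, LF line endings — so files round-trip bit-exactly
across platforms.  Coefficient tables travel as schema-checked JSON
(see :class:`dem1066.algorithm.CoefficientTable`).
"""

from __future__ import annotations

import logging
import math
from typing import List, Optional, Sequence

import pandas as pd

from .algorithm import AlgorithmResult, CoefficientTable
from .instruments import ParticipantRecord, ValidationError, build_profile

__all__ = [
    "read_records",
    "write_records",
    "write_results",
    "load_coefficients",
    "save_coefficients",
]

logger = logging.getLogger(__name__)

ITEM_COLUMNS = tuple(f"eurod_item_{i}" for i in range(1, 13))
SCALAR_COLUMNS = ("eurod_total", "recall", "cogscore", "relscore")
OPTIONAL_COLUMNS = ("group", "site", "standard_class")
MANDATORY_COLUMNS = ("id", "recall", "cogscore", "relscore")


def _cell(value):
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    return value


def _to_int(value, column: str, row_id: str) -> Optional[int]:
    value = _cell(value)
    if value is None:
        return None
    f = float(value)
    if f != int(f):
        raise ValidationError(f"row {row_id}: column {column!r} must be an integer, got {value!r}")
    return int(f)


def _to_bool(value, column: str, row_id: str) -> Optional[bool]:
    value = _cell(value)
    if value is None:
        return None
    if isinstance(value, str):
        lowered = value.strip().lower()
        if lowered in ("1", "true", "case", "yes"):
            return True
        if lowered in ("0", "false", "non_case", "no"):
            return False
        raise ValidationError(f"row {row_id}: column {column!r} must be binary, got {value!r}")
    f = float(value)
    if f not in (0.0, 1.0):
        raise ValidationError(f"row {row_id}: column {column!r} must be binary, got {value!r}")
    return bool(f)


def read_records(path, strict: bool = True) -> List[ParticipantRecord]:
    """Read and validate participant records from CSV.

    ``strict=True`` raises on the first invalid row; otherwise invalid
    rows (and repeated ids) are dropped with a logged manifest.
    """
    df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    df.columns = [c.strip().lower() for c in df.columns]
    missing_cols = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"missing mandatory column(s): {', '.join(missing_cols)}")
    has_items = all(c in df.columns for c in ITEM_COLUMNS)
    if not has_items and "eurod_total" not in df.columns:
        raise ValidationError(
            "need either eurod_total or all twelve eurod_item_* columns"
        )
    records: List[ParticipantRecord] = []
    seen = set()
    dropped: List[str] = []
    for _, row in df.iterrows():
        row_id = str(row["id"])
        try:
            if row_id in seen:
                raise ValidationError(f"duplicate id {row_id!r}")
            items = None
            if has_items:
                raw = [_to_int(row[c], c, row_id) for c in ITEM_COLUMNS]
                if all(v is None for v in raw):
                    items = None
                else:
                    items = raw
            rec = ParticipantRecord(
                id=row_id,
                eurod_items=items,
                eurod_total=_to_int(row.get("eurod_total"), "eurod_total", row_id),
                recall=_to_int(row.get("recall"), "recall", row_id),
                cogscore=_cell(row.get("cogscore")),
                relscore=_cell(row.get("relscore")),
                group=_cell(row.get("group")),
                site=_cell(row.get("site")),
                standard_class=_to_bool(row.get("standard_class"), "standard_class", row_id),
            ).validate()
            # surface score-domain violations at read time
            build_profile(rec, max_missing_eurod=12)
        except ValidationError as exc:
            if strict:
                raise
            dropped.append(f"{row_id}: {exc}")
            continue
        seen.add(row_id)
        records.append(rec)
    if dropped:
        logger.warning(
            "dropped %d invalid row(s):\n%s", len(dropped), "\n".join(dropped)
        )
    return records


def write_records(records: Sequence[ParticipantRecord], path) -> None:
    """Write records to canonical CSV (read -> write -> read is identity)."""
    has_items = any(r.eurod_items is not None for r in records)
    rows = []
    for r in records:
        row = {"id": r.id}
        if has_items:
            items = r.eurod_items or [None] * 12
            for i, col in enumerate(ITEM_COLUMNS):
                row[col] = items[i]
        row.update(
            eurod_total=r.eurod_total,
            recall=r.recall,
            cogscore=r.cogscore,
            relscore=r.relscore,
            group=r.group,
            site=r.site,
            standard_class=None if r.standard_class is None else int(r.standard_class),
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")


def write_results(results: Sequence[AlgorithmResult], path) -> None:
    """Write per-participant algorithm results to CSV."""
    rows = []
    for res in results:
        rows.append(
            {
                "id": res.id,
                "eurod_cat": res.profile.eurod,
                "recall_cat": res.profile.recall,
                "cogscore_cat": res.profile.cogscore,
                "relscore_cat": res.profile.relscore,
                "linear_predictor": res.linear_predictor,
                "probability": res.probability,
                "classification": res.classification,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")


def load_coefficients(path) -> CoefficientTable:
    return CoefficientTable.from_json(path)


def save_coefficients(table: CoefficientTable, path) -> None:
    table.to_json(path)
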