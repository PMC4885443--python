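"""Instrument score validation and ordinal categorization.

The 10/66 short dementia schedule combines four instruments:

* **Euro-D** — a 12-item depression screen (total 0-12), banded into
  quartile categories ``0``, ``1-2``, ``3-5``, ``>5``.
* **CERAD 10-word list delayed recall** — 0-10 words, banded
  ``7-10``, ``5-6``, ``4``, ``1-3``, ``0``.
* **CSI-D COGSCORE** — the participant cognitive discriminant score
  (continuous, higher = better cognition), banded at 31.84, 30.67,
  28.62 and 23.70.
* **CSI-D RELSCORE** — the informant report score (half-point
  increments, higher = more reported decline), banded ``0``,
  ``0.5-1.5``, ``2-5``, ``5.5-12``, ``>12``.

Each categorizer maps a validated raw score onto exactly one ordinal
level (reference level first); a missing score maps to ``None`` and
propagates to an indeterminate classification downstream rather than
raising.  Continuous bands are half-open ``[lower, next_lower)`` so the
partition is exhaustive even between printed band edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

__all__ = [
    "ValidationError",
    "EUROD_LEVELS",
    "RECALL_LEVELS",
    "COG_LEVELS",
    "REL_LEVELS",
    "PREDICTORS",
    "LEVELS",
    "REFERENCE_LEVELS",
    "COG_MAX",
    "REL_MAX",
    "ParticipantRecord",
    "CategoryProfile",
    "eurod_total",
    "categorize_eurod",
    "categorize_recall",
    "categorize_cogscore",
    "categorize_relscore",
    "build_profile",
    "normalize_level",
]


class ValidationError(ValueError):
    """Raised when a raw instrument value violates its domain."""


# Ordinal level labels, reference (least impaired) level first.
EUROD_LEVELS = ("0", "1-2", "3-5", ">5")
RECALL_LEVELS = ("7-10", "5-6", "4", "1-3", "0")
COG_LEVELS = (">31.84", "30.67-31.83", "28.62-30.66", "23.70-28.61", "0-23.69")
REL_LEVELS = ("0", "0.5-1.5", "2-5", "5.5-12", ">12")

PREDICTORS = ("eurod", "recall", "cogscore", "relscore")
LEVELS = {
    "eurod": EUROD_LEVELS,
    "recall": RECALL_LEVELS,
    "cogscore": COG_LEVELS,
    "relscore": REL_LEVELS,
}
REFERENCE_LEVELS = {p: LEVELS[p][0] for p in PREDICTORS}

COG_MAX = 35.0
REL_MAX = 30.0

# Lower bounds of the COGSCORE bands, most impaired first.
_COG_CUTS = (23.70, 28.62, 30.67, 31.84)

_HALF_TOL = 1e-9


def normalize_level(label: str) -> str:
    """Canonicalize a level label (en-dash sources -> ASCII hyphen)."""
    return label.replace("–", "-").replace("−", "-").strip()


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return False


def eurod_total(
    items: Sequence[Optional[int]], max_missing: int = 0
) -> Optional[int]:
    """Total the 12 Euro-D items, prorating limited missingness.

    With no missing items the exact sum is returned.  With up to
    ``max_missing`` items missing the sum is prorated to the full
    12-item scale (``sum * 12 / n_present``, rounded half-up, capped at
    12).  With more missing items the total is missing (``None``).
    """
    if not 0 <= max_missing <= 12:
        raise ValidationError(f"max_missing must be in [0, 12], got {max_missing}")
    if len(items) != 12:
        raise ValidationError(f"Euro-D has 12 items, got {len(items)}")
    present = []
    for i, v in enumerate(items, start=1):
        if _is_missing(v):
            continue
        if v not in (0, 1):
            raise ValidationError(f"Euro-D item {i} must be 0/1, got {v!r}")
        present.append(int(v))
    n_missing = 12 - len(present)
    if n_missing == 0:
        return sum(present)
    if n_missing > max_missing:
        return None
    prorated = sum(present) * 12.0 / len(present)
    return min(12, int(math.floor(prorated + 0.5)))


def categorize_eurod(total: Optional[int]) -> Optional[str]:
    """Band a Euro-D total into the quartile categories 0 / 1-2 / 3-5 / >5."""
    if _is_missing(total):
        return None
    if total != int(total) or not 0 <= total <= 12:
        raise ValidationError(f"Euro-D total must be an integer in [0, 12], got {total!r}")
    total = int(total)
    if total == 0:
        return EUROD_LEVELS[0]
    if total <= 2:
        return EUROD_LEVELS[1]
    if total <= 5:
        return EUROD_LEVELS[2]
    return EUROD_LEVELS[3]


def categorize_recall(score: Optional[int]) -> Optional[str]:
    """Band a delayed-recall word count into 7-10 / 5-6 / 4 / 1-3 / 0."""
    if _is_missing(score):
        return None
    if score != int(score) or not 0 <= score <= 10:
        raise ValidationError(f"recall must be an integer in [0, 10], got {score!r}")
    score = int(score)
    if score >= 7:
        return RECALL_LEVELS[0]
    if score >= 5:
        return RECALL_LEVELS[1]
    if score == 4:
        return RECALL_LEVELS[2]
    if score >= 1:
        return RECALL_LEVELS[3]
    return RECALL_LEVELS[4]


def categorize_cogscore(value: Optional[float]) -> Optional[str]:
    """Band a COGSCORE into the five cognitive categories.

    Bands are half-open on their lower bound: [0, 23.70), [23.70,
    28.62), [28.62, 30.67), [30.67, 31.84), [31.84, inf) — so every
    valid score, including values between printed band edges, belongs
    to exactly one band.
    """
    if _is_missing(value):
        return None
    value = float(value)
    if not 0.0 <= value <= COG_MAX:
        raise ValidationError(f"COGSCORE must be in [0, {COG_MAX}], got {value!r}")
    if value >= _COG_CUTS[3]:
        return COG_LEVELS[0]
    if value >= _COG_CUTS[2]:
        return COG_LEVELS[1]
    if value >= _COG_CUTS[1]:
        return COG_LEVELS[2]
    if value >= _COG_CUTS[0]:
        return COG_LEVELS[3]
    return COG_LEVELS[4]


def categorize_relscore(value: Optional[float], strict: bool = True) -> Optional[str]:
    """Band a RELSCORE into 0 / 0.5-1.5 / 2-5 / 5.5-12 / >12.

    Informant scores come in half-point increments, which is what makes
    the printed bands exhaustive; ``strict=False`` rounds dirty data to
    the nearest half point first.
    """
    if _is_missing(value):
        return None
    value = float(value)
    if value < 0 or value > REL_MAX:
        raise ValidationError(f"RELSCORE must be in [0, {REL_MAX}], got {value!r}")
    half_steps = value * 2.0
    if abs(half_steps - round(half_steps)) > _HALF_TOL:
        if not strict:
            value = round(half_steps) / 2.0
        else:
            raise ValidationError(
                f"RELSCORE must be a multiple of 0.5, got {value!r}"
            )
    if value == 0:
        return REL_LEVELS[0]
    if value <= 1.5:
        return REL_LEVELS[1]
    if value <= 5:
        return REL_LEVELS[2]
    if value <= 12:
        return REL_LEVELS[3]
    return REL_LEVELS[4]


@dataclass(frozen=True)
class CategoryProfile:
    """The four ordinal category assignments feeding the algorithm.

    Any component may be ``None`` (missing); a profile with a missing
    component yields an indeterminate classification.
    """

    eurod: Optional[str]
    recall: Optional[str]
    cogscore: Optional[str]
    relscore: Optional[str]

    def __post_init__(self):
        for pred in PREDICTORS:
            level = getattr(self, pred)
            if level is not None and level not in LEVELS[pred]:
                raise ValidationError(
                    f"unknown {pred} level {level!r}; expected one of {LEVELS[pred]}"
                )

    def as_dict(self) -> dict:
        return {p: getattr(self, p) for p in PREDICTORS}

    @property
    def is_complete(self) -> bool:
        return all(getattr(self, p) is not None for p in PREDICTORS)

    def missing_components(self) -> tuple:
        return tuple(p for p in PREDICTORS if getattr(self, p) is None)


@dataclass
class ParticipantRecord:
    """One participant's instrument scores plus optional study labels.

    ``eurod_items`` is the 12-vector of binary item responses when item
    data are available; ``eurod_total`` may be supplied directly.  The
    ``standard_class`` column carries an external classification (the
    standard-schedule algorithm's output) and is treated as given.
    """

    id: str
    eurod_items: Optional[Sequence[Optional[int]]] = None
    eurod_total: Optional[int] = None
    recall: Optional[int] = None
    cogscore: Optional[float] = None
    relscore: Optional[float] = None
    group: Optional[str] = None
    site: Optional[str] = None
    standard_class: Optional[bool] = None

    VALID_GROUPS = ("dementia", "depression", "high_education", "low_education")

    def validate(self) -> "ParticipantRecord":
        if self.group is not None and self.group not in self.VALID_GROUPS:
            raise ValidationError(
                f"participant {self.id}: unknown group {self.group!r}"
            )
        if self.eurod_items is not None and len(self.eurod_items) != 12:
            raise ValidationError(
                f"participant {self.id}: Euro-D needs 12 items, got {len(self.eurod_items)}"
            )
        return self

    def resolved_eurod_total(self, max_missing: int = 0) -> Optional[int]:
        """Euro-D total: the supplied total, else the (prorated) item sum."""
        if not _is_missing(self.eurod_total):
            total = self.eurod_total
            if total != int(total) or not 0 <= total <= 12:
                raise ValidationError(
                    f"participant {self.id}: Euro-D total must be in [0, 12], got {total!r}"
                )
            return int(total)
        if self.eurod_items is None:
            return None
        return eurod_total(self.eurod_items, max_missing=max_missing)


def build_profile(
    record: ParticipantRecord,
    max_missing_eurod: int = 0,
    strict_relscore: bool = True,
) -> CategoryProfile:
    """Categorize all four instruments of one participant.

    Missing scores propagate as missing components; invalid scores
    raise :class:`ValidationError` naming the participant.
    """
    try:
        return CategoryProfile(
            eurod=categorize_eurod(record.resolved_eurod_total(max_missing_eurod)),
            recall=categorize_recall(record.recall),
            cogscore=categorize_cogscore(record.cogscore),
            relscore=categorize_relscore(record.relscore, strict=strict_relscore),
        )
    except ValidationError as exc:
        raise ValidationError(f"participant {record.id}: {exc}") from exc
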