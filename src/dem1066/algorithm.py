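"""The short-form algorithm score and classification rule.

The algorithm is a calibration logistic regression over the four
ordinal category profiles: each non-reference category level carries a
log-odds coefficient (beta), the per-participant *algorithm score* is
the sum of the four applicable betas, and dementia is ascertained when
the score reaches the cut-off (published: 0.20 and above).

The published table gives the betas but not the model intercept, so
out of the box the classification operates on the linear-predictor
(coefficient-sum) scale.  When an intercept is available — from the
distributed scoring syntax or from a refit via
:mod:`dem1066.calibration` — the cut-off can equivalently be applied on
the predicted-probability scale (``cutoff_scale="probability"``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence

from scipy.special import expit

from .instruments import (
    LEVELS,
    PREDICTORS,
    REFERENCE_LEVELS,
    CategoryProfile,
    ParticipantRecord,
    ValidationError,
    build_profile,
    normalize_level,
)

__all__ = [
    "ConfigurationError",
    "CoefficientTable",
    "AlgorithmResult",
    "default_coefficients",
    "linear_predictor",
    "classify",
    "batch_classify",
    "CASE",
    "NON_CASE",
    "INDETERMINATE",
]

logger = logging.getLogger(__name__)

CASE = "case"
NON_CASE = "non_case"
INDETERMINATE = "indeterminate"

_SCALES = ("linear_predictor", "probability")


class ConfigurationError(ValueError):
    """Raised when a coefficient table is malformed or inconsistently used."""


@dataclass
class CoefficientTable:
    """Per-category log-odds coefficients plus the classification cut-off.

    ``beta[predictor][level]`` holds the log-odds contribution of each
    category level; reference levels are pinned at 0.0.  ``intercept``
    is optional because the published table omits it.  ``cutoff`` is
    interpreted on ``cutoff_scale``: either the raw coefficient sum
    (``linear_predictor``) or, when an intercept is present, the
    logistic-transformed probability (``probability``).
    """

    beta: Dict[str, Dict[str, float]]
    intercept: Optional[float] = None
    cutoff: float = 0.20
    cutoff_scale: str = "linear_predictor"
    provenance: Optional[str] = None

    def __post_init__(self):
        self.beta = {
            pred: {normalize_level(lvl): float(b) for lvl, b in levels.items()}
            for pred, levels in self.beta.items()
        }
        self.validate()

    def validate(self) -> "CoefficientTable":
        for pred in PREDICTORS:
            if pred not in self.beta:
                raise ConfigurationError(f"missing predictor {pred!r} in coefficient table")
            for level in LEVELS[pred]:
                if level not in self.beta[pred]:
                    raise ConfigurationError(
                        f"missing coefficient for {pred!r} level {level!r}"
                    )
            extra = set(self.beta[pred]) - set(LEVELS[pred])
            if extra:
                raise ConfigurationError(f"unknown {pred!r} levels {sorted(extra)}")
            ref = REFERENCE_LEVELS[pred]
            if self.beta[pred][ref] != 0.0:
                raise ConfigurationError(
                    f"reference level {pred}:{ref} must have beta 0.0, "
                    f"got {self.beta[pred][ref]}"
                )
        if self.cutoff_scale not in _SCALES:
            raise ConfigurationError(
                f"cutoff_scale must be one of {_SCALES}, got {self.cutoff_scale!r}"
            )
        if self.cutoff_scale == "probability":
            if self.intercept is None:
                raise ConfigurationError(
                    "cutoff_scale='probability' requires an intercept; supply one "
                    "(e.g. from the distributed scoring syntax) or refit the "
                    "calibration model"
                )
            if not 0.0 <= self.cutoff <= 1.0:
                raise ConfigurationError(
                    f"probability cut-off must be in [0, 1], got {self.cutoff}"
                )
        return self

    def to_dict(self) -> dict:
        return {
            "schema": "dem1066-coefficients-v1",
            "provenance": self.provenance,
            "beta": {p: dict(self.beta[p]) for p in PREDICTORS},
            "intercept": self.intercept,
            "cutoff": self.cutoff,
            "cutoff_scale": self.cutoff_scale,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CoefficientTable":
        try:
            return cls(
                beta=data["beta"],
                intercept=data.get("intercept"),
                cutoff=float(data.get("cutoff", 0.20)),
                cutoff_scale=data.get("cutoff_scale", "linear_predictor"),
                provenance=data.get("provenance"),
            )
        except KeyError as exc:
            raise ConfigurationError(f"coefficient table missing key {exc}") from exc

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, ensure_ascii=False)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "CoefficientTable":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def default_coefficients() -> CoefficientTable:
    """The published short-form coefficient table.

    Loaded from the packaged JSON so that refitted tables are drop-in
    replacements.  The intercept is absent (not published) and the
    cut-off is 0.20 on the linear-predictor scale.
    """
    text = resources.files("dem1066").joinpath(
        "data/short_form_coefficients.json"
    ).read_text(encoding="utf-8")
    return CoefficientTable.from_dict(json.loads(text))


@dataclass
class AlgorithmResult:
    """One participant's algorithm score, audit breakdown and class.

    ``linear_predictor`` is the coefficient sum; ``probability`` is its
    logistic transform including the intercept, present only when the
    intercept is known; ``classification`` is ``case`` / ``non_case``
    / ``indeterminate`` (the last whenever any profile component is
    missing).
    """

    id: Optional[str]
    profile: CategoryProfile
    linear_predictor: Optional[float]
    probability: Optional[float]
    classification: str
    contributions: Dict[str, Optional[float]] = field(default_factory=dict)

    @property
    def is_case(self) -> Optional[bool]:
        if self.classification == INDETERMINATE:
            return None
        return self.classification == CASE


def linear_predictor(
    profile: CategoryProfile, coeffs: CoefficientTable
) -> Optional[float]:
    """Sum the four beta contributions; ``None`` if any component missing."""
    if not profile.is_complete:
        return None
    return sum(coeffs.beta[p][getattr(profile, p)] for p in PREDICTORS)


def classify(
    profile: CategoryProfile,
    coeffs: CoefficientTable,
    record_id: Optional[str] = None,
) -> AlgorithmResult:
    """Apply the coefficient table and cut-off to one category profile.

    A score at or above the cut-off (on the configured scale) is a
    case; ties classify as case, reading the published "0.20+" as >=.
    """
    contributions = {
        p: (coeffs.beta[p][getattr(profile, p)] if getattr(profile, p) is not None else None)
        for p in PREDICTORS
    }
    if not profile.is_complete:
        return AlgorithmResult(
            id=record_id,
            profile=profile,
            linear_predictor=None,
            probability=None,
            classification=INDETERMINATE,
            contributions=contributions,
        )
    lp = sum(contributions.values())
    prob = None
    if coeffs.intercept is not None:
        prob = float(expit(coeffs.intercept + lp))
    if coeffs.cutoff_scale == "probability":
        if prob is None:  # guarded by validate(), kept for hand-built tables
            raise ConfigurationError(
                "cutoff_scale='probability' requires an intercept"
            )
        is_case = prob >= coeffs.cutoff
    else:
        is_case = lp >= coeffs.cutoff
    return AlgorithmResult(
        id=record_id,
        profile=profile,
        linear_predictor=lp,
        probability=prob,
        classification=CASE if is_case else NON_CASE,
        contributions=contributions,
    )


def batch_classify(
    records: Sequence[ParticipantRecord],
    coeffs: CoefficientTable,
    max_missing_eurod: int = 0,
    strict_relscore: bool = True,
) -> List[AlgorithmResult]:
    """Classify a sequence of records, preserving order.

    Validation errors are aggregated across records and raised
    together; missing scores never error — they yield indeterminate
    classifications.
    """
    results: List[AlgorithmResult] = []
    errors: List[str] = []
    for record in records:
        try:
            profile = build_profile(
                record,
                max_missing_eurod=max_missing_eurod,
                strict_relscore=strict_relscore,
            )
        except ValidationError as exc:
            errors.append(str(exc))
            continue
        results.append(classify(profile, coeffs, record_id=record.id))
    if errors:
        raise ValidationError(
            f"{len(errors)} invalid record(s):\n" + "\n".join(errors)
        )
    counts = {CASE: 0, NON_CASE: 0, INDETERMINATE: 0}
    for r in results:
        counts[r.classification] += 1
    logger.info(
        "classified %d records: %d case, %d non-case, %d indeterminate",
        len(results), counts[CASE], counts[NON_CASE], counts[INDETERMINATE],
    )
    return results
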