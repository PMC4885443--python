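"""Validation surfaces: known-group performance, inter-algorithm agreement, prevalence.

Three reporting layers mirror how short-form screening algorithms are
validated in practice:

* *known-group performance* — case rates per recruitment group, giving
  sensitivity (dementia group) and specificity (each non-dementia
  group, as 100 minus the case rate);
* *agreement* — per-site 2x2 cross-classification of the short-form
  algorithm against an external (standard-schedule) classification,
  summarised by Cohen's kappa with its asymptotic standard error;
* *prevalence* — percent classified as cases among classifiable
  participants, with missingness accounted against the full sample.

Internal values are kept at full precision; rounding to the printed
precision (1 dp percentages, 2 dp kappa) happens only in renderers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .algorithm import CASE, INDETERMINATE, NON_CASE, AlgorithmResult
from .instruments import ParticipantRecord

__all__ = [
    "EvaluationError",
    "GroupPerformance",
    "AgreementTable",
    "PrevalenceEstimate",
    "SiteComparison",
    "group_performance",
    "cohens_kappa",
    "agreement_table",
    "prevalence",
    "compare_sites",
    "as_indicator",
]

KNOWN_GROUPS = ParticipantRecord.VALID_GROUPS


class EvaluationError(ValueError):
    """Raised on degenerate evaluation input (no data, one class, ...)."""


def as_indicator(classification) -> Optional[bool]:
    """Normalize a classification to True/False/None (None = indeterminate)."""
    if classification is None:
        return None
    if isinstance(classification, AlgorithmResult):
        return classification.is_case
    if isinstance(classification, str):
        mapping = {CASE: True, NON_CASE: False, INDETERMINATE: None}
        if classification not in mapping:
            raise EvaluationError(f"unknown classification {classification!r}")
        return mapping[classification]
    if isinstance(classification, (bool,)):
        return classification
    if isinstance(classification, (int, float)):
        if isinstance(classification, float) and math.isnan(classification):
            return None
        if classification in (0, 1):
            return bool(classification)
    raise EvaluationError(f"unknown classification {classification!r}")


@dataclass
class GroupPerformance:
    """Case rates by recruitment group with derived sensitivity/specificity."""

    n: Dict[str, int]
    n_indeterminate: Dict[str, int]
    case_percent: Dict[str, float]

    @property
    def sensitivity(self) -> Optional[float]:
        return self.case_percent.get("dementia")

    @property
    def specificity(self) -> Dict[str, float]:
        return {
            g: 100.0 - pct
            for g, pct in self.case_percent.items()
            if g != "dementia"
        }

    def to_dict(self) -> dict:
        return {
            "n": dict(self.n),
            "n_indeterminate": dict(self.n_indeterminate),
            "case_percent": dict(self.case_percent),
            "sensitivity": self.sensitivity,
            "specificity": dict(self.specificity),
        }


def group_performance(
    classifications: Sequence, group_labels: Sequence[Optional[str]]
) -> GroupPerformance:
    """Cross-tabulate classifications against the recruitment groups.

    Indeterminate classifications are excluded from denominators and
    reported separately per group.
    """
    if len(classifications) != len(group_labels):
        raise EvaluationError(
            f"length mismatch: {len(classifications)} classifications vs "
            f"{len(group_labels)} group labels"
        )
    counts: Dict[str, List[int]] = {}
    for cls, group in zip(classifications, group_labels):
        if group is None:
            continue
        if group not in KNOWN_GROUPS:
            raise EvaluationError(f"unknown group label {group!r}")
        tally = counts.setdefault(group, [0, 0, 0])  # [cases, classifiable, indet]
        ind = as_indicator(cls)
        if ind is None:
            tally[2] += 1
        else:
            tally[1] += 1
            tally[0] += int(ind)
    if not counts or all(v[1] == 0 for v in counts.values()):
        raise EvaluationError("no classifiable participants in any group")
    return GroupPerformance(
        n={g: v[1] for g, v in counts.items()},
        n_indeterminate={g: v[2] for g, v in counts.items()},
        case_percent={
            g: 100.0 * v[0] / v[1] for g, v in counts.items() if v[1] > 0
        },
    )


def cohens_kappa(a: int, b: int, c: int, d: int) -> Tuple[float, float]:
    """Cohen's kappa and its asymptotic SE for a 2x2 agreement table.

    Cells follow the agreement-table convention: ``a`` both negative,
    ``b`` first-rater-only positive, ``c`` second-rater-only positive,
    ``d`` both positive.  kappa = (p_o - p_e) / (1 - p_e) with expected
    agreement from the marginal products; the SE is the large-sample
    (Fleiss-Cohen-Everitt) formula.
    """
    if min(a, b, c, d) < 0:
        raise EvaluationError("cell counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise EvaluationError("empty agreement table")
    # joint proportions: rows = rater 1 (neg, pos), cols = rater 2 (neg, pos)
    p = [[a / n, b / n], [c / n, d / n]]
    row = [p[0][0] + p[0][1], p[1][0] + p[1][1]]
    col = [p[0][0] + p[1][0], p[0][1] + p[1][1]]
    p_o = p[0][0] + p[1][1]
    p_e = row[0] * col[0] + row[1] * col[1]
    if p_e == 1.0:
        raise EvaluationError("degenerate margins: expected agreement is 1")
    kappa = (p_o - p_e) / (1 - p_e)
    # Fleiss, Cohen & Everitt large-sample variance of kappa-hat
    term1 = sum(
        p[i][i] * (1 - (row[i] + col[i]) * (1 - kappa)) ** 2 for i in (0, 1)
    )
    term2 = (1 - kappa) ** 2 * sum(
        p[i][j] * (col[i] + row[j]) ** 2 for i in (0, 1) for j in (0, 1) if i != j
    )
    term3 = (kappa - p_e * (1 - kappa)) ** 2
    var = (term1 + term2 - term3) / (n * (1 - p_e) ** 2)
    se = math.sqrt(max(var, 0.0))
    return kappa, se


@dataclass
class AgreementTable:
    """Per-site 2x2 cross-classification of two algorithms with kappa."""

    site: Optional[str]
    a: int  # both negative
    b: int  # short-form positive, standard negative
    c: int  # short-form negative, standard positive
    d: int  # both positive
    n_dropped: int = 0  # pairs with either classification indeterminate

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def percentages(self) -> Dict[str, float]:
        n = self.total
        return {k: 100.0 * getattr(self, k) / n for k in "abcd"}

    @property
    def kappa(self) -> float:
        return cohens_kappa(self.a, self.b, self.c, self.d)[0]

    @property
    def kappa_se(self) -> float:
        return cohens_kappa(self.a, self.b, self.c, self.d)[1]

    @property
    def disagreement_direction(self) -> str:
        if self.b > self.c:
            return "short-form more likely positive"
        if self.b < self.c:
            return "short-form less likely positive"
        return "balanced"

    def to_dict(self) -> dict:
        kappa, se = cohens_kappa(self.a, self.b, self.c, self.d)
        return {
            "site": self.site,
            "total": self.total,
            "both_negative": self.a,
            "short_only_positive": self.b,
            "standard_only_positive": self.c,
            "both_positive": self.d,
            "n_dropped": self.n_dropped,
            "percentages": self.percentages,
            "kappa": kappa,
            "kappa_se": se,
            "disagreement_direction": self.disagreement_direction,
        }


def agreement_table(
    short_classifications: Sequence,
    standard_classifications: Sequence,
    site: Optional[str] = None,
) -> AgreementTable:
    """Cross-tabulate short-form vs standard classifications.

    Pairs where either side is indeterminate are dropped and counted in
    ``n_dropped``.
    """
    if len(short_classifications) != len(standard_classifications):
        raise EvaluationError(
            f"length mismatch: {len(short_classifications)} short vs "
            f"{len(standard_classifications)} standard classifications"
        )
    cells = {"a": 0, "b": 0, "c": 0, "d": 0}
    dropped = 0
    for s, t in zip(short_classifications, standard_classifications):
        si, ti = as_indicator(s), as_indicator(t)
        if si is None or ti is None:
            dropped += 1
            continue
        cells["d" if si and ti else "b" if si else "c" if ti else "a"] += 1
    if sum(cells.values()) == 0:
        raise EvaluationError(f"site {site!r}: zero classifiable pairs")
    return AgreementTable(site=site, n_dropped=dropped, **cells)


@dataclass
class PrevalenceEstimate:
    """Case percentage among classifiable participants, with missingness."""

    site: Optional[str]
    n_total: int
    n_classifiable: int
    n_cases: int

    @property
    def percent_missing(self) -> float:
        return 100.0 * (self.n_total - self.n_classifiable) / self.n_total

    @property
    def prevalence_percent(self) -> float:
        return 100.0 * self.n_cases / self.n_classifiable

    def to_dict(self) -> dict:
        return {
            "site": self.site,
            "n_total": self.n_total,
            "n_classifiable": self.n_classifiable,
            "n_cases": self.n_cases,
            "percent_missing": self.percent_missing,
            "prevalence_percent": self.prevalence_percent,
        }


def prevalence(
    classifications: Sequence,
    n_total: Optional[int] = None,
    site: Optional[str] = None,
) -> PrevalenceEstimate:
    """Estimate prevalence on the classifiable participants.

    ``n_total`` defaults to the sequence length; passing a larger value
    accounts for participants missing from the classification file.
    """
    indicators = [as_indicator(c) for c in classifications]
    classifiable = [i for i in indicators if i is not None]
    if n_total is None:
        n_total = len(indicators)
    if n_total < len(classifiable):
        raise EvaluationError(
            f"n_total {n_total} smaller than classifiable count {len(classifiable)}"
        )
    if not classifiable:
        raise EvaluationError(f"site {site!r}: zero classifiable participants")
    return PrevalenceEstimate(
        site=site,
        n_total=n_total,
        n_classifiable=len(classifiable),
        n_cases=sum(classifiable),
    )


@dataclass
class SiteComparison:
    """One site's agreement table plus both algorithms' prevalences."""

    site: str
    agreement: AgreementTable
    prevalence_short: PrevalenceEstimate
    prevalence_standard: PrevalenceEstimate

    def to_dict(self) -> dict:
        return {
            "site": self.site,
            "agreement": self.agreement.to_dict(),
            "prevalence_short": self.prevalence_short.to_dict(),
            "prevalence_standard": self.prevalence_standard.to_dict(),
        }


def compare_sites(
    short_classifications: Sequence,
    standard_classifications: Sequence,
    sites: Sequence[str],
) -> List[SiteComparison]:
    """Per-site agreement and prevalence comparison, in input site order.

    Each algorithm's prevalence uses its own non-missing denominator;
    the agreement table drops pairs with either side indeterminate.
    """
    if not (len(short_classifications) == len(standard_classifications) == len(sites)):
        raise EvaluationError("classifications and sites must have equal length")
    order: List[str] = []
    by_site: Dict[str, List[Tuple]] = {}
    for s, t, site in zip(short_classifications, standard_classifications, sites):
        if site not in by_site:
            order.append(site)
            by_site[site] = []
        by_site[site].append((s, t))
    out = []
    for site in order:
        pairs = by_site[site]
        shorts = [p[0] for p in pairs]
        standards = [p[1] for p in pairs]
        out.append(
            SiteComparison(
                site=site,
                agreement=agreement_table(shorts, standards, site=site),
                prevalence_short=prevalence(shorts, n_total=len(pairs), site=site),
                prevalence_standard=prevalence(standards, n_total=len(pairs), site=site),
            )
        )
    return out
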