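"""Algorithm development machinery: split-half, calibration fit, ROC, cut-point.

The development procedure mirrors how the short-form algorithm was
derived: split the known-group pilot cohort into development and test
halves; fit a logistic regression of dementia status on the four
ordinal category variables (dummy-coded against their reference
levels) in the development half; score everyone; compute ROC curves
and AUROC per half; pick an optimal cut-point on the development ROC;
and report known-group performance of the resulting classifier.

:func:`fit_calibration` is a plain maximum-likelihood logistic fit via
statsmodels.  :func:`auroc` computes the tie-corrected concordance
probability (rank statistic) with a DeLong asymptotic confidence
interval by default; Hanley-McNeil is available as an option.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_curve

from .algorithm import CoefficientTable, batch_classify
from .evaluation import GroupPerformance, group_performance
from .instruments import (
    LEVELS,
    PREDICTORS,
    REFERENCE_LEVELS,
    CategoryProfile,
    ParticipantRecord,
    build_profile,
)

__all__ = [
    "CalibrationError",
    "SplitAssignment",
    "CalibrationFit",
    "RocResult",
    "DevelopmentReport",
    "split_halves",
    "fit_calibration",
    "auroc",
    "select_cutoff",
    "replicate_development",
]


class CalibrationError(ValueError):
    """Raised on degenerate calibration input or a failed fit."""


@dataclass
class SplitAssignment:
    """Disjoint development/test id sets, reproducible from the seed."""

    development_ids: frozenset
    test_ids: frozenset
    seed: int

    def __post_init__(self):
        if self.development_ids & self.test_ids:
            raise CalibrationError("development and test sets overlap")


def split_halves(
    records: Sequence[ParticipantRecord], fraction: float = 0.5, seed: int = 0
) -> SplitAssignment:
    """Random split into development/test halves, stratified by group.

    Records sharing a group label form a stratum (unlabelled records
    are their own stratum); within each stratum a fraction ``fraction``
    (rounded to the nearest integer, so within 1 of the exact target)
    goes to development.
    """
    if not records:
        raise CalibrationError("no records to split")
    if not 0.0 < fraction < 1.0:
        raise CalibrationError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    strata: Dict[Optional[str], List[str]] = {}
    for rec in records:
        strata.setdefault(rec.group, []).append(rec.id)
    dev: List[str] = []
    test: List[str] = []
    for group in sorted(strata, key=lambda g: (g is None, g)):
        ids = strata[group]
        k = int(math.floor(fraction * len(ids) + 0.5))
        perm = rng.permutation(len(ids))
        dev.extend(ids[i] for i in perm[:k])
        test.extend(ids[i] for i in perm[k:])
    return SplitAssignment(
        development_ids=frozenset(dev), test_ids=frozenset(test), seed=seed
    )


@dataclass
class CalibrationFit:
    """A fitted calibration model: coefficient table plus inference."""

    coefficients: CoefficientTable
    conf_int: Dict[str, Dict[str, Tuple[float, float]]]
    intercept_ci: Tuple[float, float]
    converged: bool
    n_used: int
    log_likelihood: Optional[float] = None


def _profiles_and_outcome(
    records: Sequence[ParticipantRecord],
    outcomes: Optional[Sequence[int]],
    max_missing_eurod: int,
) -> Tuple[List[CategoryProfile], np.ndarray, int]:
    """Complete-case profiles with binary outcome (default: group==dementia)."""
    if outcomes is None:
        missing_group = [r.id for r in records if r.group is None]
        if missing_group:
            raise CalibrationError(
                f"no outcome supplied and {len(missing_group)} record(s) lack a "
                f"group label (first: {missing_group[0]!r})"
            )
        outcomes = [int(r.group == "dementia") for r in records]
    if len(outcomes) != len(records):
        raise CalibrationError("outcomes and records must have equal length")
    profiles, y = [], []
    for rec, out in zip(records, outcomes):
        prof = build_profile(rec, max_missing_eurod=max_missing_eurod)
        if prof.is_complete:
            profiles.append(prof)
            y.append(int(out))
    if not profiles:
        raise CalibrationError("no complete-case records to fit on")
    return profiles, np.asarray(y), len(records) - len(profiles)


def _design_matrix(profiles: Sequence[CategoryProfile]) -> pd.DataFrame:
    """Dummy-code the four category variables against their reference levels."""
    cols = {}
    for pred in PREDICTORS:
        values = [getattr(p, pred) for p in profiles]
        for level in LEVELS[pred][1:]:
            cols[f"{pred}[{level}]"] = np.asarray(
                [v == level for v in values], dtype=float
            )
    return pd.DataFrame(cols)


def fit_calibration(
    records: Sequence[ParticipantRecord],
    outcomes: Optional[Sequence[int]] = None,
    max_missing_eurod: int = 0,
    alpha: float = 0.05,
    penalty: Optional[float] = None,
) -> CalibrationFit:
    """Fit the calibration logistic regression on complete-case records.

    The outcome defaults to membership of the dementia group.  Every
    category level of every predictor must be observed at least once.
    On (quasi-)separation the maximum-likelihood fit fails; pass
    ``penalty`` (an L1 regularization weight) to fall back to a
    penalized fit (no confidence intervals in that case).

    Returns the refitted :class:`CoefficientTable` (with intercept, on
    the probability scale by construction but serialized with the
    linear-predictor default so it is a drop-in for the published
    table) together with per-coefficient confidence intervals.
    """
    profiles, y, n_dropped = _profiles_and_outcome(
        records, outcomes, max_missing_eurod
    )
    if y.min() == y.max():
        raise CalibrationError("outcome is constant: no variation to fit")
    for pred in PREDICTORS:
        observed = {getattr(p, pred) for p in profiles}
        for level in LEVELS[pred]:
            if level not in observed:
                raise CalibrationError(
                    f"category level {pred}:{level!r} has no observations; "
                    "merge levels or supply more data"
                )
    X = _design_matrix(profiles)
    X = sm.add_constant(X, prepend=True)
    model = sm.Logit(y, X)
    if penalty is not None:
        res = model.fit_regularized(alpha=penalty, disp=0)
        converged = True
        ci = None
    else:
        # Newton first; thin cells (levels observed in one outcome class
        # only, common in small known-group samples) can make its Hessian
        # singular, in which case BFGS still finds the flat-likelihood
        # optimum with large but finite coefficients
        res = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(disp=0, maxiter=200)
                if not res.mle_retvals.get("converged", True):
                    res = None
            except Exception:
                res = None
        if res is None:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = model.fit(disp=0, method="bfgs", maxiter=1000)
            except Exception as exc:
                raise CalibrationError(
                    f"maximum-likelihood fit failed ({exc}); the data may be "
                    "separated — retry with the penalty option"
                ) from exc
            if not res.mle_retvals.get("converged", True):
                raise CalibrationError(
                    "logistic fit did not converge; the data may be separated "
                    "— retry with the penalty option"
                )
        converged = True
        try:
            ci = res.conf_int(alpha=alpha)
            if not np.isfinite(ci.to_numpy()).all():
                ci = None
        except Exception:
            ci = None  # quasi-separated: no usable covariance
    params = res.params
    beta = {pred: {REFERENCE_LEVELS[pred]: 0.0} for pred in PREDICTORS}
    conf: Dict[str, Dict[str, Tuple[float, float]]] = {p: {} for p in PREDICTORS}
    for pred in PREDICTORS:
        for level in LEVELS[pred][1:]:
            name = f"{pred}[{level}]"
            beta[pred][level] = float(params[name])
            if ci is not None:
                conf[pred][level] = (float(ci.loc[name, 0]), float(ci.loc[name, 1]))
    intercept = float(params["const"])
    intercept_ci = (
        (float(ci.loc["const", 0]), float(ci.loc["const", 1]))
        if ci is not None
        else (math.nan, math.nan)
    )
    table = CoefficientTable(
        beta=beta,
        intercept=intercept,
        cutoff=0.20,
        cutoff_scale="linear_predictor",
        provenance=f"refit on n={len(profiles)} complete-case records "
        f"({n_dropped} dropped for missingness)",
    )
    return CalibrationFit(
        coefficients=table,
        conf_int=conf,
        intercept_ci=intercept_ci,
        converged=converged,
        n_used=len(profiles),
        log_likelihood=float(res.llf) if penalty is None else None,
    )


@dataclass
class RocResult:
    """ROC points, AUROC with CI, and the selected cut-off if any.

    ``points`` are (threshold, sensitivity, 1-specificity) triples in
    increasing-threshold order, for the rule "score >= threshold is
    positive"; sensitivity is non-increasing along the list.
    """

    points: List[Tuple[float, float, float]]
    auroc: float
    auroc_ci: Tuple[float, float]
    ci_method: str
    chosen_cutoff: Optional[float] = None
    cutoff_method: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "auroc_ci": list(self.auroc_ci),
            "ci_method": self.ci_method,
            "chosen_cutoff": self.chosen_cutoff,
            "cutoff_method": self.cutoff_method,
            "n_points": len(self.points),
        }


def _delong_ci(
    pos: np.ndarray, neg: np.ndarray, auc: float, alpha: float
) -> Tuple[float, float]:
    """DeLong asymptotic CI from the placement-value variances."""
    # placement of each case among controls and vice versa
    v10 = np.array(
        [(np.sum(x > neg) + 0.5 * np.sum(x == neg)) / neg.size for x in pos]
    )
    v01 = np.array(
        [(np.sum(pos > y) + 0.5 * np.sum(pos == y)) / pos.size for y in neg]
    )
    var = (
        np.var(v10, ddof=1) / pos.size if pos.size > 1 else 0.0
    ) + (np.var(v01, ddof=1) / neg.size if neg.size > 1 else 0.0)
    z = norm.ppf(1 - alpha / 2)
    half = z * math.sqrt(max(var, 0.0))
    return (max(0.0, auc - half), min(1.0, auc + half))


def _hanley_mcneil_ci(
    n1: int, n0: int, auc: float, alpha: float
) -> Tuple[float, float]:
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)
    ) / (n1 * n0)
    z = norm.ppf(1 - alpha / 2)
    half = z * math.sqrt(max(var, 0.0))
    return (max(0.0, auc - half), min(1.0, auc + half))


def auroc(
    scores: Sequence[float],
    labels: Sequence[int],
    ci_method: str = "delong",
    alpha: float = 0.05,
) -> RocResult:
    """ROC curve and AUROC for binary labels against continuous scores.

    AUROC is the tie-corrected concordance probability (equivalent to
    the Mann-Whitney statistic scaled by the number of case/control
    pairs).  ROC points are evaluated at every distinct score.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise CalibrationError("scores and labels must have equal length")
    if set(np.unique(labels)) - {0, 1}:
        raise CalibrationError("labels must be binary 0/1")
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise CalibrationError("both classes must be present to compute a ROC")
    ranks = rankdata(scores)
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    if ci_method == "delong":
        ci = _delong_ci(scores[labels == 1], scores[labels == 0], auc, alpha)
    elif ci_method == "hanley-mcneil":
        ci = _hanley_mcneil_ci(n1, n0, auc, alpha)
    else:
        raise CalibrationError(f"unknown ci_method {ci_method!r}")
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    # roc_curve returns thresholds in decreasing order; store increasing
    points = [
        (float(t), float(s), float(f))
        for t, s, f in zip(thresholds[::-1], tpr[::-1], fpr[::-1])
    ]
    return RocResult(
        points=points, auroc=float(auc), auroc_ci=ci, ci_method=ci_method
    )


def select_cutoff(
    roc: RocResult,
    method: str = "youden",
    target_sensitivity: Optional[float] = None,
) -> float:
    """Pick a classification threshold from a ROC curve.

    ``youden`` maximizes sensitivity + specificity - 1;
    ``closest_topleft`` minimizes the Euclidean distance to the (0, 1)
    corner; ``fixed_sensitivity`` maximizes specificity subject to
    sensitivity >= ``target_sensitivity``.  Ties break toward higher
    specificity, then toward the higher threshold.  The chosen cut-off
    is recorded on ``roc``.
    """
    candidates = [(t, s, f) for t, s, f in roc.points if math.isfinite(t)]
    if not candidates:
        raise CalibrationError("degenerate ROC: no finite thresholds")
    if method == "youden":
        key = lambda p: (p[1] - p[2], -p[2], p[0])
        best = max(candidates, key=key)
    elif method == "closest_topleft":
        key = lambda p: (-((1 - p[1]) ** 2 + p[2] ** 2), -p[2], p[0])
        best = max(candidates, key=key)
    elif method == "fixed_sensitivity":
        if target_sensitivity is None:
            raise CalibrationError("fixed_sensitivity requires target_sensitivity")
        feasible = [p for p in candidates if p[1] >= target_sensitivity]
        if not feasible:
            lo = min(p[1] for p in candidates)
            hi = max(p[1] for p in candidates)
            raise CalibrationError(
                f"sensitivity {target_sensitivity} unreachable; achievable "
                f"range is [{lo:.3f}, {hi:.3f}]"
            )
        best = max(feasible, key=lambda p: (-p[2], p[0]))
    else:
        raise CalibrationError(f"unknown cut-off method {method!r}")
    roc.chosen_cutoff = best[0]
    roc.cutoff_method = method
    return best[0]


@dataclass
class DevelopmentReport:
    """Full record of one split-half development run."""

    seed: int
    split: SplitAssignment
    fit: CalibrationFit
    roc_development: RocResult
    roc_test: RocResult
    cutoff: float
    cutoff_method: str
    performance_development: GroupPerformance
    performance_test: GroupPerformance

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_development": len(self.split.development_ids),
            "n_test": len(self.split.test_ids),
            "coefficients": self.fit.coefficients.to_dict(),
            "conf_int": {
                p: {lvl: list(ci) for lvl, ci in levels.items()}
                for p, levels in self.fit.conf_int.items()
            },
            "intercept_ci": list(self.fit.intercept_ci),
            "n_fitted": self.fit.n_used,
            "roc_development": self.roc_development.to_dict(),
            "roc_test": self.roc_test.to_dict(),
            "cutoff": self.cutoff,
            "cutoff_method": self.cutoff_method,
            "performance_development": self.performance_development.to_dict(),
            "performance_test": self.performance_test.to_dict(),
        }


def _score_half(
    records: Sequence[ParticipantRecord],
    coeffs: CoefficientTable,
    max_missing_eurod: int,
) -> Tuple[np.ndarray, np.ndarray]:
    """Probabilities and dementia-group labels for complete-case records."""
    scores, labels = [], []
    for rec in records:
        prof = build_profile(rec, max_missing_eurod=max_missing_eurod)
        if not prof.is_complete:
            continue
        lp = sum(coeffs.beta[p][getattr(prof, p)] for p in PREDICTORS)
        prob = 1.0 / (1.0 + math.exp(-(coeffs.intercept + lp)))
        scores.append(prob)
        labels.append(int(rec.group == "dementia"))
    return np.asarray(scores), np.asarray(labels)


def replicate_development(
    records: Sequence[ParticipantRecord],
    seed: int,
    fraction: float = 0.5,
    cutoff_method: str = "youden",
    max_missing_eurod: int = 0,
    ci_method: str = "delong",
    penalty: Optional[float] = None,
) -> DevelopmentReport:
    """Run the whole development pipeline on a known-group cohort.

    Splits the cohort, fits the calibration model on the development
    half, computes ROC/AUROC in both halves on the predicted
    probability scale, selects the optimal cut-off on the development
    ROC, and reports known-group performance of the resulting
    classifier in both halves.  Fully reproducible from the seed.
    """
    try:
        split = split_halves(records, fraction=fraction, seed=seed)
    except CalibrationError as exc:
        raise CalibrationError(f"split: {exc}") from exc
    by_id = {r.id: r for r in records}
    dev = [by_id[i] for i in sorted(split.development_ids)]
    test = [by_id[i] for i in sorted(split.test_ids)]
    try:
        fit = fit_calibration(
            dev, max_missing_eurod=max_missing_eurod, penalty=penalty
        )
    except CalibrationError as exc:
        raise CalibrationError(f"fit: {exc}") from exc
    coeffs = fit.coefficients
    dev_scores, dev_labels = _score_half(dev, coeffs, max_missing_eurod)
    test_scores, test_labels = _score_half(test, coeffs, max_missing_eurod)
    try:
        roc_dev = auroc(dev_scores, dev_labels, ci_method=ci_method)
        cutoff = select_cutoff(roc_dev, method=cutoff_method)
        roc_test = auroc(test_scores, test_labels, ci_method=ci_method)
    except CalibrationError as exc:
        raise CalibrationError(f"roc: {exc}") from exc
    classifier = CoefficientTable(
        beta=coeffs.beta,
        intercept=coeffs.intercept,
        cutoff=cutoff,
        cutoff_scale="probability",
        provenance=coeffs.provenance,
    )
    perf_dev = group_performance(
        batch_classify(dev, classifier, max_missing_eurod=max_missing_eurod),
        [r.group for r in dev],
    )
    perf_test = group_performance(
        batch_classify(test, classifier, max_missing_eurod=max_missing_eurod),
        [r.group for r in test],
    )
    return DevelopmentReport(
        seed=seed,
        split=split,
        fit=fit,
        roc_development=roc_dev,
        roc_test=roc_test,
        cutoff=cutoff,
        cutoff_method=cutoff_method,
        performance_development=perf_dev,
        performance_test=perf_test,
    )
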