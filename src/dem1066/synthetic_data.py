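"""Synthetic cohorts with the statistical structure the pipeline assumes.

Real pilot and survey datasets of this programme are not publicly
packaged, so every stage of the toolkit is exercisable on simulated
cohorts instead:

* *pilot mode* — four known recruitment groups (dementia; depression
  without dementia; high-education and low-education controls), each
  with its own instrument-score distributions, emulating a known-group
  validation sample;
* *survey mode* — a two-class mixture at a set dementia prevalence,
  with an emulated external "standard algorithm" column whose
  sensitivity/specificity against the latent truth are configured, so
  agreement (kappa) studies have a closed-form design value;
* *model mode* — category profiles drawn from marginals with the
  outcome generated from a supplied coefficient table, for
  parameter-recovery studies of the calibration fit.

Instrument models: COGSCORE is a truncated normal on [0, 35]; RELSCORE
is a normal censored at zero and discretized to half points (censoring
rather than renormalized truncation, so control groups keep the large
point mass at zero that informant reports show); recall is
Binomial(10, p); the 12 Euro-D items are independent Bernoulli(p).
Predictors are drawn independently within group.  All randomness flows
through an explicit seed; there is no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import truncnorm

from .algorithm import CoefficientTable
from .instruments import (
    COG_MAX,
    LEVELS,
    PREDICTORS,
    REL_MAX,
    ParticipantRecord,
)

__all__ = [
    "GroupDistribution",
    "SyntheticCohortConfig",
    "default_pilot_distributions",
    "default_pilot_config",
    "default_survey_config",
    "generate_pilot_cohort",
    "generate_survey_cohort",
    "generate_from_model",
    "design_kappa",
]

INSTRUMENTS = ("eurod", "recall", "cogscore", "relscore")


@dataclass(frozen=True)
class GroupDistribution:
    """Instrument-score distribution parameters for one latent group.

    ``cog_mean``/``cog_sd`` parameterize the truncated normal COGSCORE
    on [0, 35] (higher = better cognition); ``rel_mean``/``rel_sd`` the
    zero-censored half-point RELSCORE (higher = more informant-reported
    decline; a negative mean concentrates mass at 0); ``recall_p`` the
    per-word recall probability; ``eurod_p`` the per-item endorsement
    probability of the 12 depression items.  ``missing`` maps
    instrument names to missingness rates in [0, 1).
    """

    cog_mean: float
    cog_sd: float
    rel_mean: float
    rel_sd: float
    recall_p: float
    eurod_p: float
    missing: Dict[str, float] = field(default_factory=dict)
    # minority component for atypical presentations (mild dementia,
    # impaired controls); keeps every score band occupied by both
    # outcome classes, as known-group samples are in practice
    atypical: Optional["GroupDistribution"] = None
    atypical_rate: float = 0.0

    def __post_init__(self):
        if self.cog_sd <= 0 or self.rel_sd <= 0:
            raise ValueError("standard deviations must be positive")
        if not 0 <= self.recall_p <= 1 or not 0 <= self.eurod_p <= 1:
            raise ValueError("probabilities must be in [0, 1]")
        if not 0 <= self.atypical_rate < 1:
            raise ValueError("atypical_rate must be in [0, 1)")
        if self.atypical_rate > 0 and self.atypical is None:
            raise ValueError("atypical_rate set without an atypical component")
        for inst, rate in self.missing.items():
            if inst not in INSTRUMENTS:
                raise ValueError(f"unknown instrument {inst!r} in missingness map")
            if not 0 <= rate < 1:
                raise ValueError(f"missingness rate for {inst!r} must be in [0, 1)")


def default_pilot_distributions() -> Dict[str, GroupDistribution]:
    """Default per-group instrument distributions (design calibration).

    Chosen so the published algorithm at its default cut-off separates
    the groups the way a known-group validation sample does: near-floor
    cognition and heavy informant report in the dementia group; high
    depressive symptoms with mild cognitive inefficiency in the
    depression group; education controls differing mainly in COGSCORE.
    Control groups carry near-zero depression-item endorsement because
    on the coefficient-sum scale even the mild depressive band crosses
    the published cut-off on its own.  Each group includes a small
    atypical component — mild presentations in the dementia group,
    impaired presentations in the control groups — so sensitivity sits
    below 100% and every score band carries both outcome classes.
    """
    mild_dementia = GroupDistribution(
        cog_mean=32.0, cog_sd=1.5, rel_mean=0.5, rel_sd=1.5,
        recall_p=0.70, eurod_p=0.30,
    )
    impaired_control = GroupDistribution(
        cog_mean=27.0, cog_sd=4.0, rel_mean=5.0, rel_sd=4.0,
        recall_p=0.40, eurod_p=0.30,
    )
    return {
        "dementia": GroupDistribution(
            cog_mean=22.0, cog_sd=5.0, rel_mean=7.0, rel_sd=4.0,
            recall_p=0.20, eurod_p=0.30,
            atypical=mild_dementia, atypical_rate=0.08,
        ),
        "depression": GroupDistribution(
            cog_mean=31.8, cog_sd=1.8, rel_mean=-0.5, rel_sd=2.0,
            recall_p=0.78, eurod_p=0.55,
            atypical=impaired_control, atypical_rate=0.04,
        ),
        "high_education": GroupDistribution(
            cog_mean=33.8, cog_sd=1.2, rel_mean=-3.2, rel_sd=1.5,
            recall_p=0.91, eurod_p=0.002,
            atypical=impaired_control, atypical_rate=0.01,
        ),
        "low_education": GroupDistribution(
            cog_mean=33.3, cog_sd=1.3, rel_mean=-3.0, rel_sd=1.5,
            recall_p=0.88, eurod_p=0.002,
            atypical=impaired_control, atypical_rate=0.015,
        ),
    }


def default_survey_distributions() -> Dict[str, GroupDistribution]:
    """Latent case/non-case distributions for survey mixtures.

    Cases mirror the pilot dementia group; non-cases are a community
    control blend (between the two education groups) with 1% per-
    instrument missingness on both sides.
    """
    miss = {inst: 0.01 for inst in INSTRUMENTS}
    pilot = default_pilot_distributions()
    return {
        "case": replace(pilot["dementia"], missing=dict(miss)),
        "non_case": GroupDistribution(
            cog_mean=33.2, cog_sd=1.4, rel_mean=-2.7, rel_sd=1.5,
            recall_p=0.88, eurod_p=0.005, missing=dict(miss),
            atypical=pilot["depression"].atypical, atypical_rate=0.015,
        ),
    }


@dataclass
class SyntheticCohortConfig:
    """Configuration of a synthetic cohort; the seed is mandatory.

    Pilot mode uses ``group_sizes`` + ``group_distributions``; survey
    mode uses ``n`` + ``prevalence`` + case/non-case distributions plus
    the standard-algorithm emulator's sensitivity/specificity against
    the latent truth.
    """

    seed: int
    group_sizes: Optional[Dict[str, int]] = None
    group_distributions: Optional[Dict[str, GroupDistribution]] = None
    n: Optional[int] = None
    prevalence: Optional[float] = None
    standard_sensitivity: float = 0.94
    standard_specificity: float = 0.98
    site: Optional[str] = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.group_sizes is not None:
            for g, size in self.group_sizes.items():
                if size <= 0:
                    raise ValueError(f"group size for {g!r} must be positive")
        if self.prevalence is not None and not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        for p in (self.standard_sensitivity, self.standard_specificity):
            if not 0 <= p <= 1:
                raise ValueError("emulator probabilities must be in [0, 1]")


def default_pilot_config(seed: int) -> SyntheticCohortConfig:
    """Pilot cohort at the historical group sizes (total 2885)."""
    return SyntheticCohortConfig(
        seed=seed,
        group_sizes={
            "dementia": 729,
            "depression": 702,
            "high_education": 694,
            "low_education": 760,
        },
        group_distributions=default_pilot_distributions(),
    )


def default_survey_config(
    seed: int, n: int = 2000, prevalence: float = 0.10, site: Optional[str] = None
) -> SyntheticCohortConfig:
    return SyntheticCohortConfig(
        seed=seed,
        n=n,
        prevalence=prevalence,
        group_distributions=default_survey_distributions(),
        site=site,
    )


def _draw_scores(
    rng: np.random.Generator, dist: GroupDistribution, n: int
) -> dict:
    if dist.atypical_rate > 0:
        is_atypical = rng.random(n) < dist.atypical_rate
        n_atyp = int(is_atypical.sum())
        typical = _draw_scores(rng, replace(dist, atypical=None, atypical_rate=0.0), n)
        if n_atyp:
            atyp = _draw_scores(
                rng, replace(dist.atypical, missing=dict(dist.missing)), n_atyp
            )
            idx = np.flatnonzero(is_atypical)
            typical["cog"][idx] = atyp["cog"]
            typical["rel"][idx] = atyp["rel"]
            typical["recall"][idx] = atyp["recall"]
            typical["items"][idx] = atyp["items"]
        return typical
    a = (0.0 - dist.cog_mean) / dist.cog_sd
    b = (COG_MAX - dist.cog_mean) / dist.cog_sd
    cog = truncnorm.rvs(
        a, b, loc=dist.cog_mean, scale=dist.cog_sd, size=n, random_state=rng
    )
    rel_raw = rng.normal(dist.rel_mean, dist.rel_sd, size=n)
    rel = np.clip(np.round(np.clip(rel_raw, 0.0, REL_MAX) * 2.0) / 2.0, 0.0, REL_MAX)
    recall = rng.binomial(10, dist.recall_p, size=n)
    items = rng.binomial(1, dist.eurod_p, size=(n, 12))
    masks = {
        inst: rng.random(n) < dist.missing.get(inst, 0.0) for inst in INSTRUMENTS
    }
    return {
        "cog": cog, "rel": rel, "recall": recall, "items": items, "masks": masks
    }


def _build_records(
    draws: dict, ids: Sequence[str], group: Optional[str], site: Optional[str]
) -> List[ParticipantRecord]:
    records = []
    for i, pid in enumerate(ids):
        m = draws["masks"]
        records.append(
            ParticipantRecord(
                id=pid,
                eurod_items=None if m["eurod"][i] else [int(v) for v in draws["items"][i]],
                recall=None if m["recall"][i] else int(draws["recall"][i]),
                cogscore=None if m["cogscore"][i] else float(draws["cog"][i]),
                relscore=None if m["relscore"][i] else float(draws["rel"][i]),
                group=group,
                site=site,
            ).validate()
        )
    return records


def generate_pilot_cohort(config: SyntheticCohortConfig) -> List[ParticipantRecord]:
    """Known-group cohort: one block of records per recruitment group."""
    if config.group_sizes is None:
        raise ValueError("pilot mode requires group_sizes")
    dists = config.group_distributions or default_pilot_distributions()
    rng = np.random.default_rng(config.seed)
    records: List[ParticipantRecord] = []
    counter = 0
    for group in sorted(config.group_sizes):
        if group not in dists:
            raise ValueError(f"no distribution configured for group {group!r}")
        n = config.group_sizes[group]
        draws = _draw_scores(rng, dists[group], n)
        ids = [f"p{counter + i:05d}" for i in range(n)]
        counter += n
        records.extend(_build_records(draws, ids, group, config.site))
    return records


def generate_survey_cohort(
    config: SyntheticCohortConfig,
) -> Tuple[List[ParticipantRecord], np.ndarray]:
    """Survey mixture with an emulated standard-algorithm column.

    Returns the records (with ``standard_class`` filled in) and the
    latent truth vector.  The standard column flips the truth with the
    configured 1-sensitivity / 1-specificity rates, so the design
    kappa between the column and the truth is :func:`design_kappa` of
    the same three parameters.
    """
    if config.n is None or config.prevalence is None:
        raise ValueError("survey mode requires n and prevalence")
    dists = config.group_distributions or default_survey_distributions()
    for key in ("case", "non_case"):
        if key not in dists:
            raise ValueError(f"survey mode requires a {key!r} distribution")
    rng = np.random.default_rng(config.seed)
    truth = rng.random(config.n) < config.prevalence
    records: List[ParticipantRecord] = [None] * config.n  # type: ignore[list-item]
    for key, mask in (("case", truth), ("non_case", ~truth)):
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        draws = _draw_scores(rng, dists[key], idx.size)
        recs = _build_records(
            draws, [f"s{i:05d}" for i in idx], None, config.site
        )
        for j, rec in zip(idx, recs):
            records[j] = rec
    flip = rng.random(config.n)
    for i, rec in enumerate(records):
        if truth[i]:
            rec.standard_class = bool(flip[i] < config.standard_sensitivity)
        else:
            rec.standard_class = bool(flip[i] >= config.standard_specificity)
    return records, truth.astype(int)


def design_kappa(
    prevalence: float, sensitivity: float, specificity: float
) -> float:
    """Closed-form Cohen's kappa between latent truth and the emulator.

    Computed from the 2x2 design probabilities: both-positive
    ``prev * sens``, truth-only ``prev * (1 - sens)``, emulator-only
    ``(1 - prev) * (1 - spec)``, both-negative ``(1 - prev) * spec``.
    """
    p11 = prevalence * sensitivity
    p10 = prevalence * (1 - sensitivity)
    p01 = (1 - prevalence) * (1 - specificity)
    p00 = (1 - prevalence) * specificity
    p_o = p00 + p11
    row_pos = p11 + p10  # truth positive
    col_pos = p11 + p01  # emulator positive
    p_e = row_pos * col_pos + (1 - row_pos) * (1 - col_pos)
    return (p_o - p_e) / (1 - p_e)


# numeric back-fill intervals per category level (closed bounds for draws)
_EUROD_FILL = {"0": (0, 0), "1-2": (1, 2), "3-5": (3, 5), ">5": (6, 12)}
_RECALL_FILL = {"7-10": (7, 10), "5-6": (5, 6), "4": (4, 4), "1-3": (1, 3), "0": (0, 0)}
_COG_FILL = {
    "0-23.69": (0.0, 23.70), "23.70-28.61": (23.70, 28.62),
    "28.62-30.66": (28.62, 30.67), "30.67-31.83": (30.67, 31.84),
    ">31.84": (31.84, COG_MAX),
}
_REL_FILL = {  # half-point grids
    "0": (0.0, 0.0), "0.5-1.5": (0.5, 1.5), "2-5": (2.0, 5.0),
    "5.5-12": (5.5, 12.0), ">12": (12.5, REL_MAX),
}


def generate_from_model(
    coeffs: CoefficientTable,
    intercept: float,
    n: int,
    seed: int,
    category_marginals: Optional[Dict[str, Dict[str, float]]] = None,
) -> Tuple[List[ParticipantRecord], np.ndarray]:
    """Draw profiles from marginals and outcomes from the logistic model.

    Categories are drawn independently per predictor from
    ``category_marginals`` (default: uniform over levels); the outcome
    is Bernoulli(logistic(intercept + sum of betas)).  Numeric scores
    are back-filled uniformly within each category's interval (on the
    half-point grid for the informant score) so the full
    categorize-then-fit pipeline can run on the result.
    """
    rng = np.random.default_rng(seed)
    marginals = {}
    for pred in PREDICTORS:
        levels = LEVELS[pred]
        if category_marginals and pred in category_marginals:
            probs = np.array(
                [category_marginals[pred].get(lvl, 0.0) for lvl in levels]
            )
            if probs.min() < 0 or not math.isclose(probs.sum(), 1.0, rel_tol=1e-9):
                raise ValueError(f"marginals for {pred!r} must sum to 1")
        else:
            probs = np.full(len(levels), 1.0 / len(levels))
        marginals[pred] = probs
    chosen = {
        pred: rng.choice(len(LEVELS[pred]), size=n, p=marginals[pred])
        for pred in PREDICTORS
    }
    lp = np.zeros(n)
    for pred in PREDICTORS:
        betas = np.array([coeffs.beta[pred][lvl] for lvl in LEVELS[pred]])
        lp += betas[chosen[pred]]
    prob = 1.0 / (1.0 + np.exp(-(intercept + lp)))
    outcome = (rng.random(n) < prob).astype(int)
    records = []
    for i in range(n):
        e_lvl = LEVELS["eurod"][chosen["eurod"][i]]
        r_lvl = LEVELS["recall"][chosen["recall"][i]]
        c_lvl = LEVELS["cogscore"][chosen["cogscore"][i]]
        i_lvl = LEVELS["relscore"][chosen["relscore"][i]]
        e_lo, e_hi = _EUROD_FILL[e_lvl]
        r_lo, r_hi = _RECALL_FILL[r_lvl]
        c_lo, c_hi = _COG_FILL[c_lvl]
        rl_lo, rl_hi = _REL_FILL[i_lvl]
        n_half = int(round((rl_hi - rl_lo) * 2)) + 1
        records.append(
            ParticipantRecord(
                id=f"m{i:05d}",
                eurod_total=int(rng.integers(e_lo, e_hi + 1)),
                recall=int(rng.integers(r_lo, r_hi + 1)),
                cogscore=float(rng.uniform(c_lo, c_hi)),
                relscore=float(rl_lo + 0.5 * rng.integers(0, n_half)),
            )
        )
    return records, outcome
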