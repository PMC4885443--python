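# Methods

## The algorithm

The short-form schedule ascertains dementia from four instruments:
Euro-D depression total (0–12), CERAD 10-word delayed recall (0–10),
CSI-D COGSCORE (continuous cognitive discriminant score, 0–35, higher
= better) and CSI-D RELSCORE (informant report, non-negative half
points, higher = more reported decline). Each raw score is banded into
ordinal categories (Euro-D 0 / 1–2 / 3–5 / >5; recall 7–10 / 5–6 / 4 /
1–3 / 0; COGSCORE at 31.84 / 30.67 / 28.62 / 23.70; RELSCORE 0 /
0.5–1.5 / 2–5 / 5.5–12 / >12), and a logistic-regression coefficient
is attached to every non-reference band. The algorithm score is the
sum of the four band coefficients; a score of 0.20 or more classifies
the participant as a dementia case (ties count as cases, reading the
published "0.20+" as ≥).

Two deliberate interface choices follow from what was and was not
published:

- **Cut-off scale.** The model intercept was not published, so the
  default classification operates on the coefficient-sum
  (linear-predictor) scale, which needs only published numbers. A
  probability-scale rule (`cutoff_scale="probability"`, requiring an
  intercept) is fully supported and is what `replicate_development`
  uses for refitted tables; the two rules are algebraically equivalent
  when `cutoff_lp = logit(cutoff_p) − intercept`, which is property-
  tested. Note that on the coefficient-sum scale even the mildest
  Euro-D elevation (band 1–2, β = 0.576) exceeds 0.20 on its own, so
  this default is a *liberal* rule; users with access to the
  distributed scoring syntax should configure the intercept.
- **Band edges.** The printed continuous bands (e.g. "30.67–31.83"
  then ">31.84") reflect observed discrete values and formally leave
  gaps; bands are implemented as half-open intervals
  `[lower, next_lower)` with the top band closed below at its printed
  bound, making the partition exhaustive. RELSCORE is validated to
  half-point increments, which is what makes its printed bands
  exhaustive; `strict=False` rounds dirty data to the nearest half
  point first.

Missing policy: a missing instrument yields a missing category
component and an **indeterminate** classification — never an error —
so survey missingness can be accounted in prevalence denominators.
Euro-D items default to complete-case (`max_missing_eurod=0`);
proration (`sum × 12 / n_present`, rounded half-up, capped at 12) is
available by configuration for up to a chosen number of missing items.

## Calibration machinery

`split_halves` assigns a configurable fraction (default 0.5) of each
recruitment-group stratum to the development half, so small cohorts
keep group balance. `fit_calibration` is a plain maximum-likelihood
logistic regression (statsmodels) of the binary dementia outcome on
the four dummy-coded category variables, complete cases only, with
per-coefficient Wald 95% CIs. Known-group samples routinely put an
extreme band entirely in one outcome class; when Newton's method then
fails (singular Hessian / non-convergence) the fit falls back to BFGS,
which reaches the flat-likelihood optimum with large but finite
coefficients — a usable classifier with unusable CIs, which are then
reported as unavailable. Only if BFGS also fails is a separation error
raised, with an L1-penalized fit (`penalty=`) as the documented
fallback.

AUROC is the tie-corrected rank (concordance) statistic; its default
confidence interval is DeLong's asymptotic interval from placement-
value variances, with Hanley–McNeil as an option. ROC points are
evaluated at every distinct score for the rule "score ≥ threshold".
`select_cutoff` maximizes Youden's J by default (the most common
reading of an "optimal" cut-point and fully reproducible);
`closest_topleft` and `fixed_sensitivity(s)` are alternatives. Ties
break toward higher specificity, then toward the higher threshold;
`fixed_sensitivity` returns the highest-specificity threshold whose
sensitivity still meets the floor.

`replicate_development` chains split → fit → score → ROC per half →
cut-point → known-group performance, entirely driven by one seed, and
reports the refitted coefficient table (drop-in JSON replacement for
the published one), both ROC curves, the chosen probability cut-off
and per-group case rates.

## Agreement and prevalence

Cohen's κ is computed from the 2×2 cross-classification of the two
algorithms with expected agreement from marginal products; its
standard error uses the large-sample Fleiss–Cohen–Everitt variance.
The SE convention for the original publication is unknown, so printed
SEs are not verification material; point estimates are. Pairs with
either classification indeterminate are dropped and counted.
Prevalence is cases over classifiable participants, with
`percent_missing` measured against the full sample size; each
algorithm keeps its own denominator, since the two algorithms'
missingness differs in practice.

## Synthetic cohorts

The generators exist because the original pilot and survey datasets
are not publicly packaged; they emulate the *statistical structure*
the pipeline assumes, not the datasets themselves.

Instrument models, drawn independently within group: COGSCORE
truncated normal on [0, 35]; RELSCORE a normal **censored** at zero
(not a renormalized truncation — censoring preserves the dominant
point mass at zero that informant reports of healthy controls show)
then discretized to half points; recall Binomial(10, p); Euro-D as 12
independent Bernoulli items. Each group mixes a typical component with
a small *atypical* component (mild presentations in the dementia
group, impaired presentations in controls), which keeps sensitivity
realistically below 100% and keeps every score band occupied by both
outcome classes — without it, split-half refits are routinely
quasi-separated.

Default pilot parameters (group sizes 729 / 702 / 694 / 760) were set
once from a design simulation so the *published* algorithm at its
default cut-off exhibits the known-group structure such samples are
recruited to show: dementia case rate above 90%, education-group case
rates below 15%, depression the hardest control group. Because the
coefficient-sum cut-off flags any Euro-D elevation, education controls
carry near-zero depression-item endorsement (per-item p ≈ 0.002), and
the depression group — given realistic informant-score and recall
overlap — shows a case rate near 50% under the published rule (its
specificity recovers to ≈80–90% under a refit with an intercept and a
Youden cut-off). Survey mode mixes a dementia-like case class into a
community control class at a set prevalence (default 0.10) with 1%
per-instrument missingness, and emulates an external "standard
algorithm" column by flipping the latent truth at configured
sensitivity/specificity (defaults 0.94 / 0.98), giving agreement
studies a closed-form design κ (`design_kappa`).

`generate_from_model` draws category profiles from per-predictor
marginals (default uniform), draws outcomes from
`Bernoulli(logistic(intercept + Σβ))`, and back-fills numeric scores
uniformly within each band (on the half-point grid for RELSCORE), so
the full categorize-then-refit pipeline round-trips; this is the
parameter-recovery harness.

What the generators do **not** emulate: within-person correlation
between instruments (no copula; predictors are conditionally
independent given group), site or interviewer effects, cultural or
education-dependent measurement bias, and any age/sex structure.
Passing tests therefore demonstrate that the machinery is correct and
that the published coefficients are recoverable from data generated by
the published model — not that the instruments behave this way in any
real population.

## Numerical conventions and problem sizes

Rounding to printed precision (1 dp for percentages, 2 dp for κ)
happens only in renderers; internal values are full precision. Euro-D
proration rounds half-up. Records CSV is comma-separated, UTF-8, LF,
`.` decimal, read with round-trip float parsing so read → write is
bit-identical; band labels serialize as ASCII ("5.5-12"), with
en-dash variants accepted on read. Test and acceptance runs use
cohorts of 2,885 (pilot replication), up to 10,000 (parameter
recovery) and 2,000–4,000 (survey agreement), which keep the full
suite to a few seconds while leaving all stochastic checks inside
3-standard-error tolerances of their design values.

## Known limitations

- Without the unpublished intercept, probability-scale classification
  requires a refit or an externally supplied value; the default
  coefficient-sum rule is liberal toward mild depressive symptoms.
- The κ SE formula is a convention choice (Fleiss–Cohen–Everitt);
  other software may print slightly different SEs.
- BFGS-rescued fits under quasi-separation give valid classifications
  but no usable inference for the affected bands.
- The standard algorithm is accepted as a given classification column;
  nothing in this package reproduces its internals.
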