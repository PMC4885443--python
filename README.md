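# dem1066

Scoring, calibration and validation toolkit for the **10/66 short-form
dementia diagnostic algorithm** — the brief schedule used to ascertain
dementia in epidemiological surveys in low- and middle-income countries
when the full Geriatric Mental State interview is not feasible.

The short schedule combines four instruments per participant:

| instrument | meaning | range |
|---|---|---|
| CSI-D COGSCORE | cognitive discriminant score (higher = better) | 0–35 |
| CSI-D RELSCORE | informant report of decline (higher = worse) | 0–30, half points |
| CERAD word-list delayed recall | words recalled | 0–10 |
| Euro-D | 12-item depression screen total | 0–12 |

Each score is banded into ordinal categories, every non-reference
category carries a published log-odds coefficient β, and the
participant's *algorithm score* is the coefficient sum

    score = β_eurod(cat) + β_recall(cat) + β_cog(cat) + β_rel(cat),

with dementia ascertained when the score reaches the published
cut-point of 0.20. The model intercept was never published, so the
default rule operates on the coefficient-sum (linear-predictor) scale;
when an intercept is available — e.g. from a refit — the same rule can
be applied as `logistic(intercept + score) ≥ p` on the probability
scale (`cutoff_scale="probability"`). Missing instrument scores
propagate to an *indeterminate* classification rather than erroring.

Beyond scoring, the package re-implements the machinery used to
develop and validate such algorithms:

- `dem1066.calibration` — stratified split-half sampling, the
  calibration logistic regression (dummy-coded ordinal categories),
  ROC/AUROC with DeLong confidence intervals, Youden-style cut-point
  selection, and a one-call `replicate_development` pipeline;
- `dem1066.evaluation` — known-group sensitivity/specificity tables,
  2×2 inter-algorithm agreement with Cohen's κ (and asymptotic SE),
  and per-site prevalence with missing-data accounting;
- `dem1066.synthetic_data` — seeded generators for known-group pilot
  cohorts, survey mixtures with an emulated comparison algorithm, and
  model-based cohorts for parameter-recovery studies.

## Worked example

Generate a synthetic known-group cohort at the historical group sizes
(729 dementia, 702 depression, 694 high-education, 760 low-education),
replicate the development procedure on it, and score it:

```bash
$ dem1066 simulate --mode pilot --seed 7 --output pilot.csv
wrote 2885 records to pilot.csv

$ dem1066 calibrate --records pilot.csv --seed 7 \
      --output refit.json --report report.json
development n=1443 test n=1442
AUROC development 0.990 (0.986 to 0.994); test 0.992
selected cut-off 0.1734 (youden, probability scale)
test sensitivity 98.4%
test specificity (depression) 82.1%
test specificity (high_education) 99.1%
test specificity (low_education) 98.7%
```

The cohort is split in half by group; the calibration logistic
regression is fitted on the development half; the AUROC (here 0.990)
says a random dementia-group member outscores a random control with
99% probability; the Youden-optimal probability cut-off (0.1734) is
then applied to the held-out half. Depression is the hardest control
group — the short schedule replaces a diagnostic interview with a
depression screen, so depressed controls cost the most specificity —
reproducing the qualitative ordering of the original validation.

Scoring the same file with the *published* coefficients instead:

```bash
$ dem1066 score --records pilot.csv --output scored.csv
scored 2885 participants: 1217 case, 1668 non_case
```

`scored.csv` carries each participant's category profile, per-predictor
β contributions, coefficient sum and classification. The same
operations are available as library calls (`default_coefficients`,
`batch_classify`, `replicate_development`, `agreement_table`, ...).

Agreement between two algorithms' classifications is summarised
per site by Cohen's κ:

```python
>>> from dem1066 import cohens_kappa
>>> round(cohens_kappa(2539, 54, 21, 247)[0], 2)   # a Caribbean survey site
0.85
```

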