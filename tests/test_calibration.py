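import json

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from dem1066.calibration import (
    CalibrationError,
    auroc,
    fit_calibration,
    replicate_development,
    select_cutoff,
    split_halves,
)
from dem1066.instruments import LEVELS, PREDICTORS, ParticipantRecord
from dem1066.synthetic_data import generate_from_model


def brute_force_auc(scores, labels):
    """Exhaustive case/control pair concordance count (+1/2 per tie)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestSplitHalves:
    def test_disjoint_and_complete(self, pilot_cohort):
        split = split_halves(pilot_cohort, fraction=0.5, seed=3)
        ids = {r.id for r in pilot_cohort}
        assert split.development_ids | split.test_ids == ids
        assert not split.development_ids & split.test_ids

    def test_reproducible(self, pilot_cohort):
        a = split_halves(pilot_cohort, seed=7)
        b = split_halves(pilot_cohort, seed=7)
        assert a.development_ids == b.development_ids
        assert split_halves(pilot_cohort, seed=8).development_ids != a.development_ids

    def test_stratified_by_group(self):
        records = [
            ParticipantRecord(id=f"{g}{i}", group=g)
            for g in ParticipantRecord.VALID_GROUPS
            for i in range(100)
        ]
        split = split_halves(records, fraction=0.5, seed=1)
        by_id = {r.id: r for r in records}
        for g in ParticipantRecord.VALID_GROUPS:
            n_dev = sum(1 for i in split.development_ids if by_id[i].group == g)
            assert n_dev == 50

    def test_fraction_out_of_range(self, pilot_cohort):
        with pytest.raises(CalibrationError, match="fraction"):
            split_halves(pilot_cohort, fraction=1.0, seed=0)

    def test_odd_stratum_sizes_within_one(self):
        records = [ParticipantRecord(id=str(i)) for i in range(101)]
        split = split_halves(records, fraction=0.5, seed=0)
        assert abs(len(split.development_ids) - 50.5) <= 0.5


class TestAuroc:
    def test_perfect_separation(self):
        roc = auroc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert roc.auroc == 1.0
        assert roc.auroc_ci[1] == 1.0

    def test_toy_instance_with_tie_matches_pair_count(self):
        scores = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        labels = [0, 0, 1, 0, 1, 1]
        expected = brute_force_auc(scores, labels)  # frozen oracle: 7.5/9
        assert expected == pytest.approx(7.5 / 9)
        assert auroc(scores, labels).auroc == pytest.approx(expected)

    def test_matches_brute_force_on_random_tied_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            n = int(rng.integers(4, 20))
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if labels.sum() in (0, n):
                continue
            scores = rng.integers(0, 5, size=n).astype(float)  # many ties
            result = auroc(scores, labels)
            assert result.auroc == pytest.approx(brute_force_auc(scores, labels))
            assert result.auroc == pytest.approx(roc_auc_score(labels, scores))

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(11)
        n1 = n0 = 1000
        scores = rng.normal(size=n1 + n0)
        labels = np.r_[np.ones(n1, dtype=int), np.zeros(n0, dtype=int)]
        # null SE of the rank AUROC
        se = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
        assert abs(auroc(scores, labels).auroc - 0.5) < 3 * se

    def test_invariant_under_increasing_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=60)
        labels = (rng.random(60) < 0.4).astype(int)
        base = auroc(scores, labels).auroc
        assert auroc(np.exp(scores), labels).auroc == pytest.approx(base)
        assert auroc(3 * scores + 7, labels).auroc == pytest.approx(base)

    def test_one_class_errors(self):
        with pytest.raises(CalibrationError, match="both classes"):
            auroc([1.0, 2.0], [1, 1])

    def test_ci_contains_point_estimate_and_sensitivity_monotone(self):
        rng = np.random.default_rng(3)
        scores = np.r_[rng.normal(1, 1, 50), rng.normal(0, 1, 50)]
        labels = np.r_[np.ones(50, dtype=int), np.zeros(50, dtype=int)]
        for method in ("delong", "hanley-mcneil"):
            roc = auroc(scores, labels, ci_method=method)
            assert roc.auroc_ci[0] <= roc.auroc <= roc.auroc_ci[1]
        sens = [p[1] for p in roc.points]
        assert sens == sorted(sens, reverse=True)


class TestSelectCutoff:
    def test_perfectly_separated_gives_perfect_rule(self):
        roc = auroc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        t = select_cutoff(roc, "youden")
        assert 3 < t <= 10
        assert roc.chosen_cutoff == t

    def test_youden_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            n = int(rng.integers(6, 25))
            scores = rng.integers(0, 8, size=n).astype(float)
            labels = (rng.random(n) < 0.5).astype(int)
            if labels.sum() in (0, n):
                continue
            roc = auroc(scores, labels)
            chosen = select_cutoff(roc, "youden")

            def youden(t):
                pred = scores >= t
                sens = (pred & (labels == 1)).sum() / labels.sum()
                spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
                return sens + spec - 1

            best = max(youden(t) for t in np.unique(scores))
            assert youden(chosen) == pytest.approx(best)

    def test_tie_breaks_toward_higher_specificity(self):
        # both thresholds give the same Youden J; 2 has higher specificity
        scores = [1.0, 1.0, 2.0, 2.0]
        labels = [0, 1, 0, 1]
        roc = auroc(scores, labels)
        assert select_cutoff(roc, "youden") == 2.0

    def test_fixed_sensitivity_takes_most_specific_threshold(self):
        scores = [1.0, 2.0, 3.0, 4.0, 5.0]
        labels = [0, 0, 1, 1, 1]
        roc = auroc(scores, labels)
        assert select_cutoff(roc, "fixed_sensitivity", target_sensitivity=0.94) == 3.0
        # lowering the requirement allows a stricter threshold
        assert select_cutoff(roc, "fixed_sensitivity", target_sensitivity=0.6) == 4.0

    def test_unreachable_sensitivity_lists_range(self):
        roc = auroc([1.0, 2.0], [0, 1])
        with pytest.raises(CalibrationError, match="achievable"):
            select_cutoff(roc, "fixed_sensitivity", target_sensitivity=1.5)

    def test_closest_topleft(self):
        scores = [1.0, 2.0, 3.0, 4.0]
        labels = [0, 0, 1, 1]
        roc = auroc(scores, labels)
        assert select_cutoff(roc, "closest_topleft") == 3.0


class TestFitCalibration:
    def test_recovers_known_coefficients(self, coeffs):
        records, y = generate_from_model(coeffs, intercept=-3.0, n=5000, seed=101)
        fit = fit_calibration(records, outcomes=y)
        assert fit.converged
        inside = sum(
            fit.conf_int[p][lvl][0] <= coeffs.beta[p][lvl] <= fit.conf_int[p][lvl][1]
            for p in PREDICTORS
            for lvl in LEVELS[p][1:]
        )
        assert inside >= 13  # 95% CIs over 15 levels
        assert fit.intercept_ci[0] <= -3.0 <= fit.intercept_ci[1]

    def test_bias_shrinks_with_sample_size(self, coeffs):
        errs = {}
        for n, seed in ((2000, 7), (10000, 7)):
            records, y = generate_from_model(coeffs, intercept=-2.0, n=n, seed=seed)
            fit = fit_calibration(records, outcomes=y)
            errs[n] = np.mean(
                [
                    abs(fit.coefficients.beta[p][lvl] - coeffs.beta[p][lvl])
                    for p in PREDICTORS
                    for lvl in LEVELS[p][1:]
                ]
            )
        assert errs[10000] < errs[2000]

    def test_constant_outcome_errors(self, coeffs):
        records, _ = generate_from_model(coeffs, intercept=0.0, n=200, seed=3)
        with pytest.raises(CalibrationError, match="constant"):
            fit_calibration(records, outcomes=[1] * len(records))

    def test_empty_category_level_named(self, coeffs):
        records, y = generate_from_model(
            coeffs,
            intercept=0.0,
            n=300,
            seed=4,
            category_marginals={
                "relscore": {"0": 0.5, "0.5-1.5": 0.5}  # upper bands unobserved
            },
        )
        with pytest.raises(CalibrationError, match="relscore"):
            fit_calibration(records, outcomes=y)

    def test_informant_band_order_on_pilot_cohort(self, pilot_cohort):
        # informant score worsens with dementia in the generator, so the
        # most impaired band must sit above the reference after refit
        fit = fit_calibration(pilot_cohort)
        rel = fit.coefficients.beta["relscore"]
        assert np.exp(rel[">12"]) > np.exp(rel["0"])
        assert rel[">12"] > rel["0.5-1.5"]


class TestReplicateDevelopment:
    def test_report_is_reproducible(self, pilot_cohort):
        a = replicate_development(pilot_cohort, seed=13)
        b = replicate_development(pilot_cohort, seed=13)
        assert json.dumps(a.to_dict(), sort_keys=True) == json.dumps(
            b.to_dict(), sort_keys=True
        )

    def test_development_auroc_high_on_default_cohort(self, pilot_cohort):
        report = replicate_development(pilot_cohort, seed=13)
        assert report.roc_development.auroc > 0.9
        assert report.roc_test.auroc > 0.9
        assert report.cutoff == report.roc_development.chosen_cutoff

    def test_missing_group_column_still_reports(self, pilot_cohort):
        no_depression = [r for r in pilot_cohort if r.group != "depression"]
        report = replicate_development(no_depression, seed=5)
        assert "depression" not in report.performance_test.case_percent
        assert report.performance_test.sensitivity is not None
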