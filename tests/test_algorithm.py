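import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logit

from dem1066.algorithm import (
    CASE,
    INDETERMINATE,
    NON_CASE,
    CoefficientTable,
    ConfigurationError,
    batch_classify,
    classify,
    linear_predictor,
)
from dem1066.instruments import (
    LEVELS,
    PREDICTORS,
    CategoryProfile,
    ParticipantRecord,
    ValidationError,
)

REFERENCE = CategoryProfile("0", "7-10", ">31.84", "0")


def profile_strategy(allow_missing=False):
    def level(pred):
        opts = list(LEVELS[pred]) + ([None] if allow_missing else [])
        return st.sampled_from(opts)

    return st.builds(
        CategoryProfile,
        eurod=level("eurod"),
        recall=level("recall"),
        cogscore=level("cogscore"),
        relscore=level("relscore"),
    )


class TestCoefficientTable:
    def test_published_values(self, coeffs):
        assert coeffs.beta["relscore"][">12"] == 6.088
        assert coeffs.beta["eurod"][">5"] == -1.214
        assert coeffs.beta["recall"]["7-10"] == 0.0
        assert coeffs.intercept is None
        assert coeffs.cutoff == 0.20
        assert coeffs.cutoff_scale == "linear_predictor"

    def test_eurod_betas_keep_published_non_monotone_order(self, coeffs):
        e = coeffs.beta["eurod"]
        assert e["1-2"] > e["0"] > e["3-5"] > e[">5"]
        assert [e["1-2"], e["3-5"], e[">5"]] == [0.576, -0.312, -1.214]

    def test_json_round_trip_is_value_identical(self, coeffs, tmp_path):
        path = tmp_path / "coeffs.json"
        coeffs.to_json(path)
        reloaded = CoefficientTable.from_json(path)
        assert reloaded.to_dict() == coeffs.to_dict()

    def test_en_dash_labels_accepted(self, coeffs):
        table = CoefficientTable(
            beta={
                "eurod": {"0": 0.0, "1–2": 0.5, "3–5": -0.3, ">5": -1.2},
                "recall": dict(coeffs.beta["recall"]),
                "cogscore": dict(coeffs.beta["cogscore"]),
                "relscore": dict(coeffs.beta["relscore"]),
            }
        )
        assert table.beta["eurod"]["1-2"] == 0.5

    def test_missing_level_rejected(self, coeffs):
        beta = {p: dict(coeffs.beta[p]) for p in PREDICTORS}
        del beta["recall"]["0"]
        with pytest.raises(ConfigurationError, match="recall"):
            CoefficientTable(beta=beta)

    def test_nonzero_reference_rejected(self, coeffs):
        beta = {p: dict(coeffs.beta[p]) for p in PREDICTORS}
        beta["eurod"]["0"] = 0.1
        with pytest.raises(ConfigurationError, match="reference"):
            CoefficientTable(beta=beta)

    def test_probability_scale_without_intercept_rejected(self, coeffs):
        with pytest.raises(ConfigurationError, match="intercept"):
            CoefficientTable(
                beta=coeffs.beta, cutoff=0.25, cutoff_scale="probability"
            )


class TestLinearPredictor:
    def test_reference_profile_scores_zero(self, coeffs):
        assert linear_predictor(REFERENCE, coeffs) == 0.0

    def test_hand_summed_example(self, coeffs):
        prof = CategoryProfile("1-2", "0", "0-23.69", ">12")
        assert linear_predictor(prof, coeffs) == pytest.approx(13.697)

    def test_single_negative_contribution(self, coeffs):
        prof = CategoryProfile(">5", "7-10", ">31.84", "0")
        assert linear_predictor(prof, coeffs) == pytest.approx(-1.214)

    def test_missing_component_gives_missing(self, coeffs):
        prof = CategoryProfile("0", None, ">31.84", "0")
        assert linear_predictor(prof, coeffs) is None

    @settings(max_examples=100)
    @given(profile_strategy())
    def test_equals_sum_of_contributions(self, coeffs, profile):
        result = classify(profile, coeffs)
        assert result.linear_predictor == pytest.approx(
            sum(result.contributions.values())
        )

    @settings(max_examples=100)
    @given(profile_strategy())
    def test_monotone_in_recall_and_rel(self, coeffs, profile):
        # worsening recall or the informant score never lowers the score
        base = linear_predictor(profile, coeffs)
        for pred in ("recall", "relscore"):
            levels = LEVELS[pred]
            i = levels.index(getattr(profile, pred))
            if i + 1 < len(levels):
                worse = CategoryProfile(
                    **{**profile.as_dict(), pred: levels[i + 1]}
                )
                assert linear_predictor(worse, coeffs) >= base

    def test_cogscore_published_ordering(self, coeffs):
        # the first cognitive band sits marginally below the reference
        # (printed OR 1.0); the remaining bands rise steeply
        c = [coeffs.beta["cogscore"][lvl] for lvl in LEVELS["cogscore"]]
        assert c[0] == 0.0 and -0.1 < c[1] < 0.0
        assert c[1] < c[2] < c[3] < c[4]


class TestClassify:
    def test_reference_profile_is_non_case(self, coeffs):
        assert classify(REFERENCE, coeffs).classification == NON_CASE

    def test_score_at_cutoff_is_case(self, coeffs):
        table = CoefficientTable(beta=coeffs.beta, cutoff=0.576)
        prof = CategoryProfile("1-2", "7-10", ">31.84", "0")
        assert classify(prof, table).classification == CASE

    def test_probability_scale_example(self, coeffs):
        table = CoefficientTable(
            beta=coeffs.beta, intercept=-6.0, cutoff=0.20,
            cutoff_scale="probability",
        )
        result = classify(CategoryProfile("1-2", "0", "0-23.69", ">12"), table)
        assert result.probability == pytest.approx(
            1 / (1 + math.exp(-(13.697 - 6.0)))
        )
        assert result.classification == CASE

    def test_missing_component_is_indeterminate(self, coeffs):
        prof = CategoryProfile("0", "7-10", ">31.84", None)
        result = classify(prof, coeffs)
        assert result.classification == INDETERMINATE
        assert result.linear_predictor is None
        assert result.is_case is None

    @settings(max_examples=150)
    @given(
        profile_strategy(),
        st.floats(min_value=-8, max_value=2),
        st.floats(min_value=0.01, max_value=0.99),
    )
    def test_probability_and_linear_scales_agree(self, coeffs, profile, intercept, p):
        """cutoff p on probability scale == cutoff logit(p)-intercept on lp scale."""
        prob_table = CoefficientTable(
            beta=coeffs.beta, intercept=intercept, cutoff=p,
            cutoff_scale="probability",
        )
        lp_table = CoefficientTable(
            beta=coeffs.beta, intercept=intercept,
            cutoff=float(logit(p)) - intercept, cutoff_scale="linear_predictor",
        )
        assert (
            classify(profile, prob_table).classification
            == classify(profile, lp_table).classification
        )


class TestBatchClassify:
    def test_empty_input(self, coeffs):
        assert batch_classify([], coeffs) == []

    def test_order_preserving_and_deterministic(self, coeffs):
        rec = ParticipantRecord(
            id="a", eurod_total=1, recall=3, cogscore=25.0, relscore=6.0
        )
        dup = ParticipantRecord(
            id="b", eurod_total=1, recall=3, cogscore=25.0, relscore=6.0
        )
        res = batch_classify([rec, dup], coeffs)
        assert [r.id for r in res] == ["a", "b"]
        assert res[0].classification == res[1].classification
        assert res[0].linear_predictor == res[1].linear_predictor

    def test_matches_single_record_classify(self, coeffs, pilot_cohort):
        from dem1066.instruments import build_profile

        subset = pilot_cohort[::200]
        batch = batch_classify(subset, coeffs)
        for rec, res in zip(subset, batch):
            single = classify(build_profile(rec), coeffs, record_id=rec.id)
            assert single.classification == res.classification
            assert single.linear_predictor == res.linear_predictor

    def test_aggregates_validation_errors(self, coeffs):
        bad = ParticipantRecord(
            id="bad1", eurod_total=0, recall=10, cogscore=33.0, relscore=1.75
        )
        with pytest.raises(ValidationError, match="bad1"):
            batch_classify([bad], coeffs)
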