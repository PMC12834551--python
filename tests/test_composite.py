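"""Weight redistribution, composite score, categorization, advice, assess."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from healthindex import (
    Category,
    ConfigError,
    Dass21Responses,
    EligibilityError,
    FamilyHistory,
    InputValidationError,
    InstrumentResponses,
    IpaqResponses,
    MedicalHistory,
    MissingQuestionnaireError,
    RespondentProfile,
    RiskLevel,
    SfffqResponses,
    WeightVector,
    assess,
    categorize,
    composite_score,
    effective_weights,
    generate_advice,
    normalize_domain,
)
from healthindex.instruments import FrailResponses
from healthindex.physical import RiskBand

EQUAL = WeightVector({d: 0.2 for d in ("physical_health", "mental_health", "diet", "physical_activity", "frailty")})


class TestNormalize:
    @pytest.mark.parametrize("raw, lo, hi, expected", [(0, 0, 100, 0.0), (56, 0, 100, 56.0), (10, 5, 15, 50.0)])
    def test_linear_map(self, raw, lo, hi, expected):
        assert normalize_domain(raw, lo, hi) == pytest.approx(expected)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ConfigError):
            normalize_domain(5, 5, 5)


class TestEffectiveWeights:
    def test_at_or_above_60_unchanged_and_idempotent(self):
        w = effective_weights(65, EQUAL)
        assert w.weights == EQUAL.weights
        assert effective_weights(65, w).weights == w.weights

    def test_under_60_redistributes_equally(self):
        w = effective_weights(45, EQUAL)
        assert w["frailty"] == 0.0
        for d in ("physical_health", "mental_health", "diet", "physical_activity"):
            assert w[d] == pytest.approx(0.25)

    def test_under_60_redistributes_proportionally(self):
        base = WeightVector(
            {"physical_health": 0.4, "mental_health": 0.2, "diet": 0.2,
             "physical_activity": 0.1, "frailty": 0.1}
        )
        w = effective_weights(45, base)
        assert w["physical_health"] == pytest.approx(4 / 9)
        assert w["mental_health"] == pytest.approx(2 / 9)
        assert w["diet"] == pytest.approx(2 / 9)
        assert w["physical_activity"] == pytest.approx(1 / 9)
        assert w["frailty"] == 0.0

    @given(
        st.lists(st.floats(0.01, 10), min_size=5, max_size=5),
        st.floats(18, 95),
    )
    @settings(deadline=None, max_examples=200)
    def test_output_always_sums_to_one(self, raw_weights, age):
        total = sum(raw_weights)
        base = WeightVector(
            dict(zip(("physical_health", "mental_health", "diet", "physical_activity", "frailty"),
                     [w / total for w in raw_weights]))
        )
        w = effective_weights(age, base)
        assert sum(w.weights.values()) == pytest.approx(1.0, abs=1e-9)

    def test_negative_weight_rejected(self):
        with pytest.raises(ConfigError):
            WeightVector({"physical_health": 1.2, "mental_health": -0.2, "diet": 0.0,
                          "physical_activity": 0.0, "frailty": 0.0})


class TestCompositeScore:
    def test_upper_and_lower_bounds(self):
        domains = ("physical_health", "mental_health", "diet", "physical_activity", "frailty")
        assert composite_score({d: 100.0 for d in domains}, EQUAL) == pytest.approx(100.0)
        assert composite_score({d: 0.0 for d in domains}, EQUAL) == pytest.approx(0.0)

    def test_under_60_hand_example(self):
        w = effective_weights(45, EQUAL)
        scores = {"physical_health": 91.0, "mental_health": 56.0, "diet": 56.0,
                  "physical_activity": 91.0}
        assert composite_score(scores, w) == pytest.approx(73.5)

    def test_missing_weighted_domain_is_error(self):
        with pytest.raises(InputValidationError, match="frailty"):
            composite_score({"physical_health": 50.0, "mental_health": 50.0,
                             "diet": 50.0, "physical_activity": 50.0}, EQUAL)

    def test_cutoff_derivation_from_uniform_domains(self):
        # a weighted sum of identical domain boundary scores reproduces the
        # composite cutoffs for ANY weights summing to 1
        rng = np.random.default_rng(0)
        for _ in range(50):
            raw = rng.dirichlet(np.ones(5))
            w = WeightVector(dict(zip(
                ("physical_health", "mental_health", "diet", "physical_activity", "frailty"),
                raw.tolist())))
            assert composite_score({d: 82.0 for d in w.weights}, w) == pytest.approx(82.0)
            assert composite_score({d: 30.0 for d in w.weights}, w) == pytest.approx(30.0)

    @given(
        st.lists(st.floats(0, 100), min_size=5, max_size=5),
        st.lists(st.floats(0.01, 5), min_size=5, max_size=5),
    )
    @settings(deadline=None, max_examples=300)
    def test_composite_always_within_0_100(self, scores, raw_w):
        domains = ("physical_health", "mental_health", "diet", "physical_activity", "frailty")
        total = sum(raw_w)
        w = WeightVector(dict(zip(domains, [x / total for x in raw_w])))
        c = composite_score(dict(zip(domains, scores)), w)
        assert -1e-9 <= c <= 100 + 1e-9


class TestCategorize:
    @pytest.mark.parametrize(
        "score, category",
        [
            (82, Category.healthy),
            (81, Category.at_risk),
            (31, Category.at_risk),
            (30, Category.poor_health),
            (0, Category.poor_health),
            (100, Category.healthy),
            (81.5, Category.healthy),  # rounds half-up to 82
            (30.4, Category.poor_health),
            (30.5, Category.at_risk),
        ],
    )
    def test_boundaries_and_rounding(self, score, category):
        assert categorize(score) is category

    def test_all_integers_covered_exactly_once(self):
        counts = {c: 0 for c in Category}
        for i in range(101):
            counts[categorize(float(i))] += 1
        assert counts[Category.poor_health] == 31  # 0..30
        assert counts[Category.at_risk] == 51  # 31..81
        assert counts[Category.healthy] == 19  # 82..100

    def test_out_of_range_rejected(self):
        with pytest.raises(InputValidationError):
            categorize(101.0)


class TestAdvice:
    def test_all_low_gives_no_cards(self, config):
        bands = {f: RiskBand(f, RiskLevel.low) for f in config.factors}
        assert generate_advice(bands, config) == []

    def test_overweight_card_text(self, config):
        bands = {"bmi": RiskBand("bmi", RiskLevel.moderate)}
        cards = generate_advice(bands, config)
        assert len(cards) == 1
        assert cards[0].message_key == "bmi.moderate"
        assert "overweight" in cards[0].message_text

    def test_cards_follow_config_factor_order(self, config):
        bands = {
            "smoking": RiskBand("smoking", RiskLevel.high),
            "bmi": RiskBand("bmi", RiskLevel.high),
        }
        cards = generate_advice(bands, config)
        assert [c.factor_id for c in cards] == ["bmi", "smoking"]  # config order

    def test_locale_fallback(self, config):
        bands = {"waist": RiskBand("waist", RiskLevel.high)}
        cards_ms = generate_advice(bands, config, locale="ms")
        cards_en = generate_advice(bands, config, locale="en")
        assert cards_ms[0].message_text == cards_en[0].message_text  # ms falls back

    def test_ms_catalog_used_when_present(self, config):
        bands = {"bmi": RiskBand("bmi", RiskLevel.moderate)}
        (card,) = generate_advice(bands, config, locale="ms")
        assert "BMI anda" in card.message_text


class TestAssess:
    def test_best_case_45_year_old(self, config, healthy_profile, healthy_responses):
        res = assess(healthy_profile, healthy_responses, config)
        assert res.composite == pytest.approx(91.0)
        assert res.category is Category.healthy
        assert res.advice == []
        assert set(res.domain_scores) == {
            "physical_health", "mental_health", "diet", "physical_activity"
        }  # frailty not administered under 60
        assert res.completeness == 1.0

    def test_worst_attainable_case_45_year_old(self, config):
        profile = RespondentProfile(
            age=45, sex="male", height=170.0, weight=95.0, waist=110.0,
            sbp=160.0, dbp=100.0, ldl=5.0, fbg=8.0, hba1c=7.5,
            smoking="current", drinks_alcohol=True, std_drinks_per_week=30.0,
            family_history=FamilyHistory(diabetes=True),
            medical_history=MedicalHistory(diabetes=True),
        )
        responses = InstrumentResponses(
            dass21=Dass21Responses(items=(3,) * 21),
            ipaq_sf=IpaqResponses(),
            sfffq=SfffqResponses(fruit=0, vegetables=0, oily_fish=0, non_milk_sugar=5, fat=5),
        )
        res = assess(profile, responses, config)
        # family history tops out at moderate, so the physical domain floors
        # at (8*15 + 56)/9 rather than 15
        expected_physical = (8 * 15 + 56) / 9
        assert res.domain_scores["physical_health"].raw == pytest.approx(expected_physical)
        assert res.composite == pytest.approx(0.25 * (expected_physical + 3 * 15))
        assert res.category is Category.poor_health

    def test_under_18_is_ineligible(self, config, healthy_profile, healthy_responses):
        profile = dataclasses.replace(healthy_profile, age=17)
        with pytest.raises(EligibilityError):
            assess(profile, healthy_responses, config)

    def test_frail_required_from_60(self, config, healthy_profile, healthy_responses):
        older = dataclasses.replace(healthy_profile, age=60)
        with pytest.raises(MissingQuestionnaireError, match="frail"):
            assess(older, healthy_responses, config)
        with_frail = dataclasses.replace(
            healthy_responses, frail=FrailResponses(False, False, False, 0, False)
        )
        res = assess(older, with_frail, config)
        assert "frailty" in res.domain_scores
        assert res.composite == pytest.approx(91.0)

    def test_missing_questionnaire_named(self, config, healthy_profile, healthy_responses):
        broken = dataclasses.replace(healthy_responses, sfffq=None)
        with pytest.raises(MissingQuestionnaireError, match="sfffq"):
            assess(healthy_profile, broken, config)

    def test_assess_is_deterministic(self, config, healthy_profile, healthy_responses):
        a = assess(healthy_profile, healthy_responses, config)
        b = assess(healthy_profile, healthy_responses, config)
        assert a == b

    def test_improving_one_domain_never_lowers_composite(self, config, healthy_profile):
        # diet moves high -> moderate -> low while everything else is fixed
        def responses(sugar_freq):
            return InstrumentResponses(
                dass21=Dass21Responses(items=(0,) * 21),
                ipaq_sf=IpaqResponses(vigorous_days=5, vigorous_min_per_day=60.0),
                sfffq=SfffqResponses(fruit=0, vegetables=0, oily_fish=0,
                                     non_milk_sugar=sugar_freq, fat=sugar_freq),
            )

        composites = [
            assess(healthy_profile, responses(freq), config).composite
            for freq in (5, 2, 0)  # worst -> middling -> best sugar/fat intake
        ]
        assert composites == sorted(composites)
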