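"""Guideline banding and scoreboard aggregation of the physical domain."""

import dataclasses

import numpy as np
import pytest

from healthindex import (
    ConfigError,
    FamilyHistory,
    InputValidationError,
    MedicalHistory,
    RespondentProfile,
    RiskLevel,
    UnscorableDomainError,
    band_factor,
    compute_bmi,
    score_physical_health,
)
from healthindex.config import PHYSICAL_FACTORS
from healthindex.physical import RiskBand, aggregate_scoreboard


def make_profile(**overrides):
    base = dict(
        age=45, sex="male", height=175.0, weight=70.0, waist=85.0,
        sbp=110.0, dbp=70.0, ldl=2.0, fbg=4.8, hba1c=5.0,
    )
    base.update(overrides)
    return RespondentProfile(**base)


class TestBmi:
    @pytest.mark.parametrize(
        "height, weight, expected",
        [(170.0, 57.8, 20.0), (100.0, 25.0, 25.0), (160.0, 76.8, 30.0)],
    )
    def test_arithmetic(self, height, weight, expected):
        assert compute_bmi(height, weight) == pytest.approx(expected)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(InputValidationError):
            compute_bmi(0, 70)


class TestBandTables:
    @pytest.mark.parametrize(
        "bmi, band",
        [
            (17.0, RiskLevel.moderate),  # underweight
            (18.5, RiskLevel.low),
            (24.9, RiskLevel.low),
            (25.0, RiskLevel.moderate),
            (29.9, RiskLevel.moderate),  # largest overweight value
            (30.0, RiskLevel.high),
        ],
    )
    def test_bmi_bands(self, config, bmi, band):
        profile = make_profile(height=100.0, weight=bmi)  # BMI == weight at 1 m
        assert band_factor("bmi", profile, config).band is band

    def test_bmi_bands_exhaustive_on_fine_grid(self, config):
        for bmi in np.arange(10.0, 60.0, 0.05):
            profile = make_profile(height=100.0, weight=float(bmi))
            rb = band_factor("bmi", profile, config)
            assert rb.band in (RiskLevel.low, RiskLevel.moderate, RiskLevel.high)

    @pytest.mark.parametrize(
        "sex, waist, band",
        [
            ("male", 93.9, RiskLevel.low),
            ("male", 94.0, RiskLevel.moderate),
            ("male", 102.0, RiskLevel.high),
            ("female", 79.9, RiskLevel.low),
            ("female", 80.0, RiskLevel.moderate),
            ("female", 88.0, RiskLevel.high),
        ],
    )
    def test_waist_bands_sex_specific(self, config, sex, waist, band):
        assert band_factor("waist", make_profile(sex=sex, waist=waist), config).band is band

    @pytest.mark.parametrize(
        "sbp, dbp, diagnosed, band",
        [
            (118.0, 76.0, False, RiskLevel.low),
            (120.0, 76.0, False, RiskLevel.moderate),
            (118.0, 80.0, False, RiskLevel.moderate),
            (140.0, 76.0, False, RiskLevel.high),
            (118.0, 90.0, False, RiskLevel.high),
            (110.0, 70.0, True, RiskLevel.high),
        ],
    )
    def test_blood_pressure_bands(self, config, sbp, dbp, diagnosed, band):
        profile = make_profile(sbp=sbp, dbp=dbp, diagnosed_hypertension=diagnosed)
        assert band_factor("blood_pressure", profile, config).band is band

    @pytest.mark.parametrize(
        "ldl, diagnosed, band",
        [
            (2.5, False, RiskLevel.low),
            (2.6, False, RiskLevel.moderate),
            (4.1, False, RiskLevel.moderate),
            (4.2, False, RiskLevel.high),
            (2.0, True, RiskLevel.high),
        ],
    )
    def test_ldl_bands(self, config, ldl, diagnosed, band):
        profile = make_profile(ldl=ldl, diagnosed_dyslipidemia=diagnosed)
        assert band_factor("ldl", profile, config).band is band

    @pytest.mark.parametrize(
        "fbg, hba1c, band",
        [
            (5.5, 5.6, RiskLevel.low),
            (5.6, 5.6, RiskLevel.moderate),  # FBG prediabetic
            (5.5, 5.7, RiskLevel.moderate),  # HbA1c prediabetic
            (7.0, 5.6, RiskLevel.high),
            (5.5, 6.5, RiskLevel.high),  # worse of the two wins
        ],
    )
    def test_glycaemia_worse_of_two(self, config, fbg, hba1c, band):
        assert band_factor("glycaemia", make_profile(fbg=fbg, hba1c=hba1c), config).band is band

    def test_glycaemia_diagnosis_bands_high(self, config):
        profile = make_profile(fbg=None, hba1c=None, diagnosed_t2dm=True)
        assert band_factor("glycaemia", profile, config).band is RiskLevel.high

    @pytest.mark.parametrize(
        "smoking, band",
        [("never", RiskLevel.low), ("former", RiskLevel.moderate), ("current", RiskLevel.high)],
    )
    def test_smoking_bands(self, config, smoking, band):
        assert band_factor("smoking", make_profile(smoking=smoking), config).band is band

    @pytest.mark.parametrize(
        "sex, drinks, per_week, band",
        [
            ("male", False, None, RiskLevel.low),
            ("male", True, 0.0, RiskLevel.low),
            ("male", True, 14.0, RiskLevel.moderate),
            ("male", True, 15.0, RiskLevel.high),
            ("female", True, 7.0, RiskLevel.moderate),
            ("female", True, 8.0, RiskLevel.high),
        ],
    )
    def test_alcohol_weekly_limits(self, config, sex, drinks, per_week, band):
        profile = make_profile(sex=sex, drinks_alcohol=drinks, std_drinks_per_week=per_week)
        assert band_factor("alcohol", profile, config).band is band

    def test_family_history_never_bands_high(self, config):
        none = make_profile()
        some = make_profile(family_history=FamilyHistory(premature_cvd=True))
        assert band_factor("family_history", none, config).band is RiskLevel.low
        assert band_factor("family_history", some, config).band is RiskLevel.moderate

    def test_medical_history_unsure_vs_diagnosed(self, config):
        unsure = make_profile(medical_history=MedicalHistory(unsure=True))
        diagnosed = make_profile(medical_history=MedicalHistory(cancer=True))
        assert band_factor("medical_history", make_profile(), config).band is RiskLevel.low
        assert band_factor("medical_history", unsure, config).band is RiskLevel.moderate
        assert band_factor("medical_history", diagnosed, config).band is RiskLevel.high

    def test_missing_biomarker_without_diagnosis_is_missing(self, config):
        profile = make_profile(sbp=None, dbp=None)
        rb = band_factor("blood_pressure", profile, config)
        assert rb.missing and rb.band is None

    def test_unknown_factor_is_config_error(self, config):
        with pytest.raises(ConfigError, match="unknown factor"):
            band_factor("sleep", make_profile(), config)


class TestScoreboard:
    def test_all_low_profile_scores_91(self, config):
        score = score_physical_health(make_profile(), config)
        assert score.raw == pytest.approx(91.0)
        assert score.band is RiskLevel.low
        assert score.completeness == 1.0

    def test_all_high_bands_score_15(self, config):
        bands = {f: RiskBand(f, RiskLevel.high) for f in PHYSICAL_FACTORS}
        score = aggregate_scoreboard(bands, config, "physical_health")
        assert score.raw == pytest.approx(15.0)
        assert score.band is RiskLevel.high

    def test_missing_factors_renormalize(self, config):
        # half the biomarkers missing, remainder all low -> raw still 91
        profile = make_profile(waist=None, sbp=None, dbp=None, ldl=None, fbg=None, hba1c=None)
        score = score_physical_health(profile, config)
        assert score.raw == pytest.approx(91.0)
        assert score.completeness == pytest.approx(5 / 9)

    def test_deleting_factor_at_the_mean_leaves_raw_unchanged(self, config):
        bands = {f: RiskBand(f, RiskLevel.moderate) for f in PHYSICAL_FACTORS}
        full = aggregate_scoreboard(bands, config, "physical_health")
        bands["waist"] = RiskBand("waist", None, missing=True)
        reduced = aggregate_scoreboard(bands, config, "physical_health")
        assert reduced.raw == pytest.approx(full.raw)

    def test_all_missing_is_unscorable(self, config):
        bands = {f: RiskBand(f, None, missing=True) for f in PHYSICAL_FACTORS}
        with pytest.raises(UnscorableDomainError):
            aggregate_scoreboard(bands, config, "physical_health")

    def test_worsening_one_band_never_raises_raw(self, config):
        rng = np.random.default_rng(3)
        levels = [RiskLevel.low, RiskLevel.moderate, RiskLevel.high]
        for _ in range(200):
            bands = {
                f: RiskBand(f, levels[int(rng.integers(3))]) for f in PHYSICAL_FACTORS
            }
            base = aggregate_scoreboard(bands, config, "physical_health").raw
            f = PHYSICAL_FACTORS[int(rng.integers(len(PHYSICAL_FACTORS)))]
            idx = levels.index(bands[f].band)
            if idx == 2:
                continue
            worse = dict(bands)
            worse[f] = RiskBand(f, levels[idx + 1])
            assert aggregate_scoreboard(worse, config, "physical_health").raw <= base

    def test_raw_is_convex_combination_of_points(self, config):
        rng = np.random.default_rng(4)
        levels = [RiskLevel.low, RiskLevel.moderate, RiskLevel.high]
        for _ in range(200):
            bands = {
                f: RiskBand(f, levels[int(rng.integers(3))]) for f in PHYSICAL_FACTORS
            }
            raw = aggregate_scoreboard(bands, config, "physical_health").raw
            assert config.points_map.high <= raw <= config.points_map.low
            assert 0.0 <= raw <= 100.0


class TestProfileValidation:
    def test_sbp_must_exceed_dbp(self):
        with pytest.raises(InputValidationError, match="systolic"):
            make_profile(sbp=80.0, dbp=90.0)

    def test_nonpositive_anthropometrics_rejected(self):
        with pytest.raises(InputValidationError):
            make_profile(height=0.0)

    def test_unknown_sex_rejected(self):
        with pytest.raises(InputValidationError):
            make_profile(sex="other")
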