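"""Scoring configuration: band tables, points map, weights, thresholds, advice.

Every numeric rule of the scoring engine lives here so that divergent
guideline dialects (e.g. Asian-population BMI/waist cutpoints, alternative
instrument scoring conventions) can be swapped in without code changes.
The field defaults ARE the shipped default configuration;
:func:`default_config` returns them and ``data/default.yaml`` is the same
document serialized for reference and for ``--config`` round-trips.
"""

from __future__ import annotations

import hashlib
import json
from enum import Enum
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import ConfigError

DOMAINS = ("physical_health", "mental_health", "diet", "physical_activity", "frailty")

#: The 13 scored factors: nine physical-health/lifestyle factors plus the
#: four questionnaire-backed domain factors.
PHYSICAL_FACTORS = (
    "bmi",
    "waist",
    "blood_pressure",
    "ldl",
    "glycaemia",
    "smoking",
    "alcohol",
    "family_history",
    "medical_history",
)
INSTRUMENT_FACTORS = ("mental_health", "diet", "physical_activity", "frailty")
ALL_FACTORS = PHYSICAL_FACTORS + INSTRUMENT_FACTORS


class RiskLevel(str, Enum):
    """Three-level risk band shared by every factor and domain."""

    low = "low"
    moderate = "moderate"
    high = "high"


class Category(str, Enum):
    """Composite-score category."""

    healthy = "healthy"
    at_risk = "at_risk"
    poor_health = "poor_health"


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class PointsMap(_StrictModel):
    """Scoreboard points per risk band.

    Defaults are the midpoints of the three composite category ranges
    (82-100, 31-81, 0-30) so a uniformly banded profile lands inside the
    matching category.
    """

    low: float = 91.0
    moderate: float = 56.0
    high: float = 15.0

    @model_validator(mode="after")
    def _ordered(self) -> "PointsMap":
        if not (0 <= self.high < self.moderate < self.low <= 100):
            raise ValueError("points must satisfy 0 <= high < moderate < low <= 100")
        return self


class CategoryThresholds(_StrictModel):
    """Composite cutoffs: healthy >= healthy_min, poor <= poor_max (rounded)."""

    healthy_min: int = 82
    at_risk_min: int = 31
    at_risk_max: int = 81
    poor_max: int = 30

    @model_validator(mode="after")
    def _ordered(self) -> "CategoryThresholds":
        ok = (
            0 <= self.poor_max < self.at_risk_min <= self.at_risk_max < self.healthy_min <= 100
            and self.at_risk_min == self.poor_max + 1
            and self.healthy_min == self.at_risk_max + 1
        )
        if not ok:
            raise ValueError(
                "thresholds must partition 0..100 as poor <= poor_max < at_risk <= "
                "at_risk_max < healthy_min"
            )
        return self


class BmiBands(_StrictModel):
    """WHO BMI cutpoints; half-open bands [lo, hi)."""

    underweight_max: float = 18.5  # below -> moderate (underweight)
    overweight_min: float = 25.0  # [overweight_min, obese_min) -> moderate
    obese_min: float = 30.0  # >= -> high


class WaistBandsBySex(_StrictModel):
    moderate_min: float
    high_min: float


class WaistBands(_StrictModel):
    """WHO waist-circumference action levels (cm), sex-specific."""

    male: WaistBandsBySex = WaistBandsBySex(moderate_min=94.0, high_min=102.0)
    female: WaistBandsBySex = WaistBandsBySex(moderate_min=80.0, high_min=88.0)


class BloodPressureBands(_StrictModel):
    """mmHg cutoffs: high if SBP>=sbp_high or DBP>=dbp_high (or diagnosed)."""

    sbp_moderate: float = 120.0
    dbp_moderate: float = 80.0
    sbp_high: float = 140.0
    dbp_high: float = 90.0


class LdlBands(_StrictModel):
    """LDL cholesterol (mmol/L): low < moderate_min, high above high_above."""

    moderate_min: float = 2.6
    high_above: float = 4.1


class GlycaemiaBands(_StrictModel):
    """Fasting glucose (mmol/L) and HbA1c (%); the worse of the two counts."""

    fbg_moderate: float = 5.6
    fbg_high: float = 7.0
    hba1c_moderate: float = 5.7
    hba1c_high: float = 6.5


class AlcoholLimits(_StrictModel):
    """Weekly standard-drink limits (2/day men, 1/day women as weekly totals)."""

    weekly_male: float = 14.0
    weekly_female: float = 7.0


class Dass21Policy(_StrictModel):
    """DASS-21 severity tables and the severity -> domain-risk policy.

    ``*_cuts`` are inclusive upper bounds on the doubled (0-42) subscale raw
    for normal/mild/moderate/severe; anything above the last bound is
    extremely severe.
    """

    depression_cuts: tuple[int, int, int, int] = (9, 13, 20, 27)
    anxiety_cuts: tuple[int, int, int, int] = (7, 9, 14, 19)
    stress_cuts: tuple[int, int, int, int] = (14, 18, 25, 33)
    # domain risk: high if any subscale at/above this severity, moderate if
    # any at/above the moderate trigger, else low
    high_if_at_least: str = "severe"
    moderate_if_at_least: str = "mild"


class IpaqPolicy(_StrictModel):
    """IPAQ-SF data-processing rules: MET weights, 10-min floor, 180-min cap."""

    met_vigorous: float = 8.0
    met_moderate: float = 4.0
    met_walking: float = 3.3
    daily_min_floor: float = 10.0
    daily_min_cap: float = 180.0


class SfffqPolicy(_StrictModel):
    """Diet-quality scoring: frequency->score tables and DQS cutpoints.

    Each food group is answered on a 6-level ordinal frequency scale
    (0 never/rarely, 1 <1/week, 2 1/week, 3 2-3/week, 4 4-6/week,
    5 daily or more); the table maps the level to a 1-3 component score.
    Protective groups score up with frequency; sugar and fat score down.
    """

    fruit: tuple[int, ...] = (1, 1, 2, 2, 3, 3)
    vegetables: tuple[int, ...] = (1, 1, 2, 2, 3, 3)
    oily_fish: tuple[int, ...] = (1, 2, 3, 3, 3, 3)
    non_milk_sugar: tuple[int, ...] = (3, 3, 2, 2, 1, 1)
    fat: tuple[int, ...] = (3, 3, 2, 2, 1, 1)
    low_min_dqs: int = 12  # dqs >= 12 -> low risk
    moderate_min_dqs: int = 8  # 8-11 -> moderate; <= 7 -> high

    @model_validator(mode="after")
    def _tables_valid(self) -> "SfffqPolicy":
        for name in ("fruit", "vegetables", "oily_fish", "non_milk_sugar", "fat"):
            table = getattr(self, name)
            if not table or any(s not in (1, 2, 3) for s in table):
                raise ValueError(f"sfffq table {name!r} must map onto scores 1..3")
            if not set(table) == {1, 2, 3}:
                raise ValueError(f"sfffq table {name!r} must be surjective onto {{1,2,3}}")
        if not self.moderate_min_dqs < self.low_min_dqs:
            raise ValueError("DQS cutpoints must satisfy moderate_min < low_min")
        return self


class FrailPolicy(_StrictModel):
    """FRAIL scale: illnesses component scores when count > illness_threshold."""

    illness_threshold: int = 5
    illness_list_length: int = 11


class AdviceConfig(_StrictModel):
    """Locale-keyed message catalogs; keys are '<factor>.<band>'."""

    default_locale: str = "en"
    catalogs: dict[str, dict[str, str]]


def _default_advice_en() -> dict[str, str]:
    msgs: dict[str, str] = {
        "bmi.moderate": (
            "Your BMI is in the overweight category. Being overweight puts you at "
            "risk of developing chronic diseases such as diabetes, hypertension, and "
            "coronary heart disease. Start adopting a healthy and active lifestyle "
            "before it's too late! Lowering your BMI starts with increasing your "
            "physical activity and sticking to a healthy eating plan."
        ),
        "bmi.high": (
            "Your BMI is in the obese category, which strongly increases your risk "
            "of chronic diseases. Please discuss a weight-management plan with a "
            "health professional."
        ),
        "waist.moderate": (
            "Your waist circumference is above the recommended level, a sign of "
            "central adiposity. Increasing activity and improving diet can reduce it."
        ),
        "waist.high": (
            "Your waist circumference is substantially raised, which increases "
            "metabolic and cardiovascular risk. Consider seeking professional advice."
        ),
        "blood_pressure.moderate": (
            "Your blood pressure is raised. Reducing salt intake, staying active and "
            "monitoring your readings can help bring it down."
        ),
        "blood_pressure.high": (
            "Your blood pressure is in the hypertensive range (or you have been "
            "diagnosed with hypertension). Please follow up with your care provider."
        ),
        "ldl.moderate": (
            "Your LDL cholesterol is borderline raised. A diet lower in saturated "
            "fat and regular exercise can improve it."
        ),
        "ldl.high": (
            "Your LDL cholesterol is high (or you have been diagnosed with "
            "dyslipidemia). Please discuss lipid management with your doctor."
        ),
        "glycaemia.moderate": (
            "Your blood glucose markers are in the prediabetic range. Lifestyle "
            "changes now can prevent progression to diabetes."
        ),
        "glycaemia.high": (
            "Your blood glucose markers are in the diabetic range (or you have been "
            "diagnosed with type 2 diabetes). Please follow your care plan."
        ),
        "smoking.moderate": (
            "As a former smoker you have already reduced your risk; staying "
            "smoke-free keeps it falling."
        ),
        "smoking.high": (
            "Smoking is a leading cause of chronic disease. Quitting is the single "
            "most effective step you can take for your health."
        ),
        "alcohol.moderate": (
            "You drink within the recommended limit. Keeping intake low, with "
            "alcohol-free days, protects your long-term health."
        ),
        "alcohol.high": (
            "Your alcohol intake exceeds the recommended weekly limit, raising your "
            "risk of liver disease, cancer and high blood pressure. Consider cutting "
            "down."
        ),
        "family_history.moderate": (
            "You have a family history of chronic disease. Regular screening and a "
            "healthy lifestyle are especially important for you."
        ),
        "family_history.high": (
            "Your family history indicates elevated inherited risk; regular "
            "screening is strongly advised."
        ),
        "medical_history.moderate": (
            "You are unsure of your medical history. A health screening would "
            "clarify your risk profile."
        ),
        "medical_history.high": (
            "You have a diagnosed chronic condition. Keeping up with your care plan "
            "and healthy habits helps prevent complications."
        ),
        "mental_health.moderate": (
            "Your questionnaire suggests mild to moderate emotional distress. "
            "Self-care, social support and stress management can help."
        ),
        "mental_health.high": (
            "Your questionnaire suggests severe emotional distress. Please consider "
            "reaching out to a mental-health professional."
        ),
        "diet.moderate": (
            "Your diet quality has room to improve. Aim for more fruit, vegetables "
            "and oily fish, and less sugar and fat-rich food."
        ),
        "diet.high": (
            "Your diet quality is low, which contributes to chronic-disease risk. "
            "Small sustained changes — more fibre, less sugar and saturated fat — "
            "make a real difference."
        ),
        "physical_activity.moderate": (
            "Your activity level is moderate. Building up towards higher weekly "
            "activity brings further health benefits."
        ),
        "physical_activity.high": (
            "Your physical activity level is low. Even brisk walking most days of "
            "the week substantially reduces chronic-disease risk."
        ),
        "frailty.moderate": (
            "You show early signs of frailty (pre-frail). Strength exercise and "
            "good nutrition can prevent progression."
        ),
        "frailty.high": (
            "You screen as frail, which raises the risk of adverse health outcomes. "
            "Please discuss an assessment with your care provider."
        ),
    }
    return msgs


def _default_advice_ms() -> dict[str, str]:
    # Malay catalog hook: partial by design; lookups fall back to the default
    # locale for missing keys.
    return {
        "bmi.moderate": (
            "BMI anda berada dalam kategori berlebihan berat badan. Mulakan gaya "
            "hidup sihat dan aktif sebelum terlambat!"
        ),
        "smoking.high": (
            "Merokok adalah punca utama penyakit kronik. Berhenti merokok adalah "
            "langkah paling berkesan untuk kesihatan anda."
        ),
    }


class ScoringConfig(_StrictModel):
    """The complete scoring configuration (13 factors across 5 domains)."""

    config_version: int = 1
    eligibility_min_age: int = 18
    # inclusive: frailty is administered from this age upward
    frailty_min_age: int = 60
    factors: tuple[str, ...] = ALL_FACTORS
    domain_weights: dict[str, float] = Field(
        default_factory=lambda: {d: 0.2 for d in DOMAINS}
    )
    # per-factor weights inside the physical-health scoreboard (equal default)
    physical_factor_weights: dict[str, float] = Field(
        default_factory=lambda: {f: 1.0 for f in PHYSICAL_FACTORS}
    )
    points_map: PointsMap = PointsMap()
    thresholds: CategoryThresholds = CategoryThresholds()
    # domain raw range used by min-max normalization (identity under defaults)
    domain_score_range: tuple[float, float] = (0.0, 100.0)
    asian_cutoffs: bool = False
    bmi_bands: BmiBands = BmiBands()
    bmi_bands_asian: BmiBands = BmiBands(underweight_max=18.5, overweight_min=23.0, obese_min=27.5)
    waist_bands: WaistBands = WaistBands()
    waist_bands_asian: WaistBands = WaistBands(
        male=WaistBandsBySex(moderate_min=85.0, high_min=90.0),
        female=WaistBandsBySex(moderate_min=74.0, high_min=80.0),
    )
    blood_pressure_bands: BloodPressureBands = BloodPressureBands()
    ldl_bands: LdlBands = LdlBands()
    glycaemia_bands: GlycaemiaBands = GlycaemiaBands()
    alcohol_limits: AlcoholLimits = AlcoholLimits()
    # "unsure" past medical history scores moderate (policy choice, not a
    # guideline value)
    unsure_history_band: RiskLevel = RiskLevel.moderate
    dass21: Dass21Policy = Dass21Policy()
    ipaq: IpaqPolicy = IpaqPolicy()
    sfffq: SfffqPolicy = SfffqPolicy()
    frail: FrailPolicy = FrailPolicy()
    advice: AdviceConfig = Field(
        default_factory=lambda: AdviceConfig(
            catalogs={"en": _default_advice_en(), "ms": _default_advice_ms()}
        )
    )

    @model_validator(mode="after")
    def _invariants(self) -> "ScoringConfig":
        if set(self.domain_weights) != set(DOMAINS):
            raise ValueError(f"domain_weights must cover exactly {DOMAINS}")
        if any(w < 0 for w in self.domain_weights.values()):
            raise ValueError("domain weights must be non-negative")
        total = sum(self.domain_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"domain weights must sum to 1 (got {total!r})")
        if set(self.factors) != set(ALL_FACTORS) or len(self.factors) != len(ALL_FACTORS):
            raise ValueError(f"factors must be a permutation of the 13 factors {ALL_FACTORS}")
        if set(self.physical_factor_weights) != set(PHYSICAL_FACTORS):
            raise ValueError("physical_factor_weights must cover the 9 physical factors")
        if any(w <= 0 for w in self.physical_factor_weights.values()):
            raise ValueError("physical factor weights must be positive")
        lo, hi = self.domain_score_range
        if not hi > lo:
            raise ValueError("domain_score_range must be a non-degenerate interval")
        default_cat = self.advice.catalogs.get(self.advice.default_locale)
        if default_cat is None:
            raise ValueError(
                f"default locale {self.advice.default_locale!r} has no advice catalog"
            )
        for factor in self.factors:
            for band in ("moderate", "high"):
                key = f"{factor}.{band}"
                if key not in default_cat:
                    raise ValueError(f"advice catalog missing message for ({factor}, {band})")
        return self

    # -- derived views ---------------------------------------------------

    def bmi_table(self) -> BmiBands:
        return self.bmi_bands_asian if self.asian_cutoffs else self.bmi_bands

    def waist_table(self) -> WaistBands:
        return self.waist_bands_asian if self.asian_cutoffs else self.waist_bands

    def digest(self) -> str:
        """Stable sha256 digest of the config for result provenance."""
        cached = self.__dict__.get("_digest_cache")
        if cached is None:
            payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
            cached = hashlib.sha256(payload.encode()).hexdigest()
            # frozen model: bypass pydantic's setattr guard for the cache slot
            object.__setattr__(self, "_digest_cache", cached)
        return cached


def default_config() -> ScoringConfig:
    """The shipped default configuration."""
    return ScoringConfig()


def load_config(path: str | Path) -> ScoringConfig:
    """Load and validate a YAML or JSON configuration file.

    Omitted fields take their defaults; invariant violations raise
    :class:`~healthindex.errors.ConfigError` with field-level messages.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"config {path} is not valid YAML/JSON: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config {path} must be a mapping at top level")
    try:
        return ScoringConfig(**data)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        )
        raise ConfigError(f"invalid config {path}: {details}") from exc


def packaged_default_path() -> Path:
    """Path of the serialized default configuration shipped with the package."""
    return Path(__file__).parent / "data" / "default.yaml"


def dump_config(config: ScoringConfig, path: str | Path) -> None:
    """Serialize a configuration to YAML."""
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False, allow_unicode=True)
    )
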