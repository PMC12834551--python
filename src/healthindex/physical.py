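"""Guideline-based banding of physical-health and lifestyle factors.

The nine factors (BMI, waist circumference, blood pressure, LDL, glycaemia,
smoking, alcohol, family history, medical history) are each banded
low / moderate / high against guideline cutoffs, then aggregated into the
physical-health domain score through the scoreboard: band -> points,
weighted average over the factors that could be scored.

Units are fixed: cm, kg, mmHg, mmol/L, % (HbA1c). No unit conversion is
attempted; mg/dL inputs are the caller's error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .config import PHYSICAL_FACTORS, RiskLevel, ScoringConfig
from .errors import ConfigError, InputValidationError, UnscorableDomainError

_RISK_ORDER = {RiskLevel.low: 0, RiskLevel.moderate: 1, RiskLevel.high: 2}


def worst_band(*bands: RiskLevel) -> RiskLevel:
    return max(bands, key=_RISK_ORDER.__getitem__)


@dataclass(frozen=True)
class FamilyHistory:
    diabetes: bool = False
    premature_cvd: bool = False
    familial_hyperlipidemia: bool = False

    @property
    def any(self) -> bool:
        return self.diabetes or self.premature_cvd or self.familial_hyperlipidemia


@dataclass(frozen=True)
class MedicalHistory:
    cvd: bool = False
    cerebrovascular: bool = False
    cancer: bool = False
    hypertension: bool = False
    diabetes: bool = False
    unsure: bool = False

    @property
    def any_diagnosed(self) -> bool:
        return self.cvd or self.cerebrovascular or self.cancer or self.hypertension or self.diabetes


@dataclass(frozen=True)
class RespondentProfile:
    """Demographics, anthropometrics, biomarkers and lifestyle flags.

    Optional biomarker fields left as ``None`` mark the factor as missing
    (unless a diagnosis flag bands it anyway). ``emr_prefilled`` records
    which fields were auto-populated from a medical record — provenance
    only, no effect on scoring.
    """

    age: float
    sex: str  # "male" | "female"
    height: float  # cm
    weight: float  # kg
    ethnicity: str = ""
    waist: Optional[float] = None  # cm
    smoking: str = "never"  # never | former | current
    drinks_alcohol: bool = False
    std_drinks_per_week: Optional[float] = None
    family_history: FamilyHistory = field(default_factory=FamilyHistory)
    medical_history: MedicalHistory = field(default_factory=MedicalHistory)
    sbp: Optional[float] = None  # mmHg
    dbp: Optional[float] = None  # mmHg
    diagnosed_hypertension: bool = False
    ldl: Optional[float] = None  # mmol/L
    diagnosed_dyslipidemia: bool = False
    diagnosed_t2dm: bool = False
    fbg: Optional[float] = None  # mmol/L
    hba1c: Optional[float] = None  # %
    emr_prefilled: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise InputValidationError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.smoking not in ("never", "former", "current"):
            raise InputValidationError(
                f"smoking must be never/former/current, got {self.smoking!r}"
            )
        for name in ("age", "height", "weight"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or isinstance(v, bool) or v <= 0:
                raise InputValidationError(f"{name} must be a positive number, got {v!r}")
        for name in ("waist", "sbp", "dbp", "ldl", "fbg", "hba1c", "std_drinks_per_week"):
            v = getattr(self, name)
            if v is not None and (not isinstance(v, (int, float)) or isinstance(v, bool) or v < 0):
                raise InputValidationError(f"{name} must be non-negative when present, got {v!r}")
        for name in ("waist", "sbp", "dbp", "ldl", "fbg", "hba1c"):
            v = getattr(self, name)
            if v is not None and v == 0:
                raise InputValidationError(f"{name} must be positive when present")
        if self.sbp is not None and self.dbp is not None and not self.sbp > self.dbp:
            raise InputValidationError(
                f"systolic pressure must exceed diastolic (got {self.sbp}/{self.dbp})"
            )
        if isinstance(self.emr_prefilled, (set, list, tuple)):
            object.__setattr__(self, "emr_prefilled", frozenset(self.emr_prefilled))

    @property
    def bmi(self) -> float:
        return compute_bmi(self.height, self.weight)


@dataclass(frozen=True)
class RiskBand:
    factor_id: str
    band: Optional[RiskLevel]
    missing: bool = False


@dataclass(frozen=True)
class DomainScore:
    domain: str
    raw: float  # 0-100
    band: RiskLevel
    completeness: float  # scored factors / applicable factors


def compute_bmi(height_cm: float, weight_kg: float) -> float:
    """Body-mass index in kg/m^2; unrounded (display convention is 1 dp)."""
    if height_cm <= 0 or weight_kg <= 0:
        raise InputValidationError("height and weight must be positive")
    return weight_kg / (height_cm / 100.0) ** 2


# ---------------------------------------------------------------------------
# Per-factor banders
# ---------------------------------------------------------------------------


def _band_bmi(profile: RespondentProfile, config: ScoringConfig) -> RiskBand:
    t = config.bmi_table()
    bmi = profile.bmi
    if bmi >= t.obese_min:
        band = RiskLevel.high
    elif bmi >= t.overweight_min or bmi < t.underweight_max:
        band = RiskLevel.moderate
    else:
        band = RiskLevel.low
    return RiskBand("bmi", band)


def _band_waist(profile: RespondentProfile, config: ScoringConfig) -> RiskBand:
    if profile.waist is None:
        return RiskBand("waist", None, missing=True)
    t = getattr(config.waist_table(), profile.sex)
    if profile.waist >= t.high_min:
        band = RiskLevel.high
    elif profile.waist >= t.moderate_min:
        band = RiskLevel.moderate
    else:
        band = RiskLevel.low
    return RiskBand("waist", band)


def _band_blood_pressure(profile: RespondentProfile, config: ScoringConfig) -> RiskBand:
    t = config.blood_pressure_bands
    if profile.diagnosed_hypertension:
        return RiskBand("blood_pressure", RiskLevel.high)
    if profile.sbp is None or profile.dbp is None:
        return RiskBand("blood_pressure", None, missing=True)
    if profile.sbp >= t.sbp_high or profile.dbp >= t.dbp_high:
        band = RiskLevel.high
    elif profile.sbp >= t.sbp_moderate or profile.dbp >= t.dbp_moderate:
        band = RiskLevel.moderate
    else:
        band = RiskLevel.low
    return RiskBand("blood_pressure", band)


def _band_ldl(profile: RespondentProfile, config: ScoringConfig) -> RiskBand:
    t = config.ldl_bands
    if profile.diagnosed_dyslipidemia:
        return RiskBand("ldl", RiskLevel.high)
    if profile.ldl is None:
        return RiskBand("ldl", None, missing=True)
    if profile.ldl > t.high_above:
        band = RiskLevel.high
    elif profile.ldl >= t.moderate_min:
        band = RiskLevel.moderate
    else:
        band = RiskLevel.low
    return RiskBand("ldl", band)


def _band_glycaemia(profile: RespondentProfile, config: ScoringConfig) -> RiskBand:
    """FBG and HbA1c proxy the same construct; the worse of the two counts."""
    t = config.glycaemia_bands
    if profile.diagnosed_t2dm:
        return RiskBand("glycaemia", RiskLevel.high)
    if profile.fbg is None and profile.hba1c is None:
        return RiskBand("glycaemia", None, missing=True)
    bands = []
    if profile.fbg is not None:
        if profile.fbg >= t.fbg_high:
            bands.append(RiskLevel.high)
        elif profile.fbg >= t.fbg_moderate:
            bands.append(RiskLevel.moderate)
        else:
            bands.append(RiskLevel.low)
    if profile.hba1c is not None:
        if profile.hba1c >= t.hba1c_high:
            bands.append(RiskLevel.high)
        elif profile.hba1c >= t.hba1c_moderate:
            bands.append(RiskLevel.moderate)
        else:
            bands.append(RiskLevel.low)
    return RiskBand("glycaemia", worst_band(*bands))


def _band_smoking(profile: RespondentProfile, config: ScoringConfig) -> RiskBand:
    band = {
        "never": RiskLevel.low,
        "former": RiskLevel.moderate,
        "current": RiskLevel.high,
    }[profile.smoking]
    return RiskBand("smoking", band)


def _band_alcohol(profile: RespondentProfile, config: ScoringConfig) -> RiskBand:
    if not profile.drinks_alcohol:
        return RiskBand("alcohol", RiskLevel.low)
    if profile.std_drinks_per_week is None:
        return RiskBand("alcohol", None, missing=True)
    if profile.std_drinks_per_week == 0:
        return RiskBand("alcohol", RiskLevel.low)
    limit = (
        config.alcohol_limits.weekly_male
        if profile.sex == "male"
        else config.alcohol_limits.weekly_female
    )
    band = RiskLevel.moderate if profile.std_drinks_per_week <= limit else RiskLevel.high
    return RiskBand("alcohol", band)


def _band_family_history(profile: RespondentProfile, config: ScoringConfig) -> RiskBand:
    # no high band: family history is a predisposition, not a diagnosis
    band = RiskLevel.moderate if profile.family_history.any else RiskLevel.low
    return RiskBand("family_history", band)


def _band_medical_history(profile: RespondentProfile, config: ScoringConfig) -> RiskBand:
    if profile.medical_history.any_diagnosed:
        band = RiskLevel.high
    elif profile.medical_history.unsure:
        band = config.unsure_history_band
    else:
        band = RiskLevel.low
    return RiskBand("medical_history", band)


_BANDERS = {
    "bmi": _band_bmi,
    "waist": _band_waist,
    "blood_pressure": _band_blood_pressure,
    "ldl": _band_ldl,
    "glycaemia": _band_glycaemia,
    "smoking": _band_smoking,
    "alcohol": _band_alcohol,
    "family_history": _band_family_history,
    "medical_history": _band_medical_history,
}


def band_factor(factor_id: str, profile: RespondentProfile, config: ScoringConfig) -> RiskBand:
    """Band one physical-health/lifestyle factor against its guideline table."""
    try:
        bander = _BANDERS[factor_id]
    except KeyError:
        raise ConfigError(
            f"unknown factor {factor_id!r}; physical factors are {PHYSICAL_FACTORS}"
        ) from None
    return bander(profile, config)


def band_all_factors(profile: RespondentProfile, config: ScoringConfig) -> dict[str, RiskBand]:
    """Band all nine physical-health factors, preserving config factor order."""
    return {
        f: band_factor(f, profile, config) for f in config.factors if f in _BANDERS
    }


def domain_band_from_raw(raw: float, config: ScoringConfig) -> RiskLevel:
    """Shared domain band boundaries, applied to the half-up-rounded raw."""
    from .composite import round_half_up  # shared rounding policy

    r = round_half_up(raw)
    t = config.thresholds
    if r >= t.healthy_min:
        return RiskLevel.low
    if r >= t.at_risk_min:
        return RiskLevel.moderate
    return RiskLevel.high


def aggregate_scoreboard(
    bands: dict[str, RiskBand], config: ScoringConfig, domain: str
) -> DomainScore:
    """Scoreboard aggregation: points per band, weight-averaged, renormalized
    over non-missing factors."""
    points = {
        RiskLevel.low: config.points_map.low,
        RiskLevel.moderate: config.points_map.moderate,
        RiskLevel.high: config.points_map.high,
    }
    num = 0.0
    den = 0.0
    scored = 0
    for factor_id, rb in bands.items():
        if rb.missing or rb.band is None:
            continue
        w = config.physical_factor_weights.get(factor_id, 1.0)
        num += w * points[rb.band]
        den += w
        scored += 1
    if den == 0:
        raise UnscorableDomainError(
            f"domain {domain!r} has no scorable factor (all {len(bands)} missing)"
        )
    raw = num / den
    completeness = scored / len(bands) if bands else 0.0
    return DomainScore(
        domain=domain, raw=raw, band=domain_band_from_raw(raw, config), completeness=completeness
    )


def score_physical_health(profile: RespondentProfile, config: ScoringConfig) -> DomainScore:
    """Band the nine physical factors and aggregate them into the domain score."""
    return aggregate_scoreboard(band_all_factors(profile, config), config, "physical_health")
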