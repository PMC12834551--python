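"""The composite Health Index: HI = sum_i S_i * w_i.

Five domain scores S_i (each 0-100 after min-max normalization, the identity
under the default scoreboard) are combined by a weight vector w_i. Weights
are equal by default; for respondents under the frailty age the frailty
weight is 0 and the remaining weights are redistributed proportionally.
The composite is rounded half-up and stratified as healthy (>= 82),
at risk (31-81) or poor health (<= 30). One advice card is emitted per
factor banded moderate or high.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .config import (
    DOMAINS,
    INSTRUMENT_FACTORS,
    Category,
    RiskLevel,
    ScoringConfig,
)
from .errors import (
    ConfigError,
    EligibilityError,
    InputValidationError,
    MissingQuestionnaireError,
)
from .instruments import (
    Dass21Responses,
    DietScore,
    FrailResponses,
    FrailtyScore,
    IpaqResponses,
    MentalHealthScore,
    PhysicalActivityScore,
    SfffqResponses,
    score_dass21,
    score_frail,
    score_ipaq_sf,
    score_sfffq,
)
from .physical import (
    DomainScore,
    RespondentProfile,
    RiskBand,
    band_all_factors,
    domain_band_from_raw,
)


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero (half-up for x>=0)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class WeightVector:
    """Domain weights: non-negative, summing to 1."""

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        w = dict(self.weights)
        object.__setattr__(self, "weights", w)
        unknown = set(w) - set(DOMAINS)
        if unknown:
            raise ConfigError(f"unknown domains in weight vector: {sorted(unknown)}")
        if any(v < 0 for v in w.values()):
            raise ConfigError(f"weights must be non-negative: {w}")
        total = sum(w.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"weights must sum to 1, got {total!r}")

    def __getitem__(self, domain: str) -> float:
        return self.weights.get(domain, 0.0)

    @property
    def support(self) -> tuple[str, ...]:
        return tuple(d for d in DOMAINS if self.weights.get(d, 0.0) > 0)


@dataclass(frozen=True)
class AdviceCard:
    factor_id: str
    band: RiskLevel
    message_key: str
    message_text: str


@dataclass(frozen=True)
class InstrumentResponses:
    """Raw answers to the four questionnaires; frail only applies from the
    frailty age upward."""

    dass21: Optional[Dass21Responses] = None
    ipaq_sf: Optional[IpaqResponses] = None
    sfffq: Optional[SfffqResponses] = None
    frail: Optional[FrailResponses] = None


@dataclass(frozen=True)
class HealthIndexResult:
    composite: float  # unrounded, for downstream statistics
    composite_rounded: int  # what a user would see
    category: Category
    domain_scores: dict[str, DomainScore]
    factor_bands: dict[str, RiskBand]
    instrument_scores: dict[str, object]
    advice: list[AdviceCard]
    completeness: float
    config_digest: str
    package_version: str


def normalize_domain(raw_points: float, min_points: float, max_points: float) -> float:
    """Min-max normalization of a domain raw onto 0-100.

    The identity when the native range already is (0, 100), which is the
    default scoreboard's case.
    """
    if not max_points > min_points:
        raise ConfigError(
            f"degenerate normalization range ({min_points}, {max_points})"
        )
    if not min_points <= raw_points <= max_points:
        raise InputValidationError(
            f"raw score {raw_points} outside its range [{min_points}, {max_points}]"
        )
    return 100.0 * (raw_points - min_points) / (max_points - min_points)


def effective_weights(age: float, base: WeightVector, frailty_min_age: float = 60) -> WeightVector:
    """Apply the under-age frailty rule to a base weight vector.

    At or above the frailty age the base weights are returned unchanged
    (idempotent). Below it, frailty gets weight 0 and the other weights are
    each divided by their collective sum, so they keep their proportions and
    the vector still sums to 1.
    """
    if age >= frailty_min_age:
        return base
    others = {d: w for d, w in base.weights.items() if d != "frailty"}
    total = sum(others.values())
    if total <= 0:
        raise ConfigError("cannot redistribute: non-frailty weights sum to 0")
    redistributed = {d: w / total for d, w in others.items()}
    redistributed["frailty"] = 0.0
    return WeightVector(redistributed)


def composite_score(domain_scores: Mapping[str, float], weights: WeightVector) -> float:
    """Weighted sum of domain scores over the weight vector's support."""
    total = 0.0
    for domain in DOMAINS:
        w = weights[domain]
        if w == 0.0:
            continue
        if domain not in domain_scores:
            raise InputValidationError(
                f"domain {domain!r} carries weight {w} but has no score"
            )
        s = domain_scores[domain]
        if not 0.0 <= s <= 100.0:
            raise InputValidationError(f"domain score {domain!r}={s} outside [0, 100]")
        total += w * s
    return total


def categorize(composite: float, config: ScoringConfig | None = None) -> Category:
    """Stratify a composite score: the rounded integer decides the category."""
    config = config or ScoringConfig()
    if not 0.0 <= composite <= 100.0:
        raise InputValidationError(f"composite {composite} outside [0, 100]")
    r = round_half_up(composite)
    t = config.thresholds
    if r >= t.healthy_min:
        return Category.healthy
    if r >= t.at_risk_min:
        return Category.at_risk
    return Category.poor_health


def generate_advice(
    risk_bands: Mapping[str, RiskBand],
    config: ScoringConfig,
    locale: str | None = None,
) -> list[AdviceCard]:
    """One advice card per factor banded moderate or high, in config factor
    order; locale falls back to the default-language catalog per message."""
    locale = locale or config.advice.default_locale
    catalog = config.advice.catalogs.get(locale, {})
    fallback = config.advice.catalogs[config.advice.default_locale]
    cards: list[AdviceCard] = []
    for factor_id in config.factors:
        rb = risk_bands.get(factor_id)
        if rb is None or rb.missing or rb.band in (None, RiskLevel.low):
            continue
        key = f"{factor_id}.{rb.band.value}"
        text = catalog.get(key, fallback.get(key))
        if text is None:
            raise ConfigError(f"advice catalog has no message for ({factor_id}, {rb.band.value})")
        cards.append(AdviceCard(factor_id=factor_id, band=rb.band, message_key=key, message_text=text))
    return cards


def _points_for(band: RiskLevel, config: ScoringConfig) -> float:
    return {
        RiskLevel.low: config.points_map.low,
        RiskLevel.moderate: config.points_map.moderate,
        RiskLevel.high: config.points_map.high,
    }[band]


def _instrument_domain_score(band: RiskLevel, domain: str, config: ScoringConfig) -> DomainScore:
    raw = _points_for(band, config)
    lo, hi = config.domain_score_range
    raw = normalize_domain(raw, lo, hi)
    return DomainScore(domain=domain, raw=raw, band=domain_band_from_raw(raw, config), completeness=1.0)


def assess(
    profile: RespondentProfile,
    responses: InstrumentResponses,
    config: ScoringConfig | None = None,
    locale: str | None = None,
) -> HealthIndexResult:
    """Full pipeline: instruments -> domain scores -> weights -> composite ->
    category -> advice.

    FRAIL is required exactly for respondents at or above the frailty age;
    DASS-21, IPAQ-SF and SFFFQ are always required (incomplete questionnaires
    are rejected, not imputed).
    """
    from . import __version__

    config = config or ScoringConfig()
    if profile.age < config.eligibility_min_age:
        raise EligibilityError(
            f"respondent age {profile.age} is below the qualifying age "
            f"({config.eligibility_min_age})"
        )
    frail_required = profile.age >= config.frailty_min_age
    for name, resp in (("dass21", responses.dass21), ("ipaq_sf", responses.ipaq_sf), ("sfffq", responses.sfffq)):
        if resp is None:
            raise MissingQuestionnaireError(f"required questionnaire missing: {name}")
    if frail_required and responses.frail is None:
        raise MissingQuestionnaireError(
            f"required questionnaire missing: frail (age {profile.age} >= {config.frailty_min_age})"
        )

    mental = score_dass21(responses.dass21, config.dass21)
    activity = score_ipaq_sf(responses.ipaq_sf, config.ipaq)
    diet = score_sfffq(responses.sfffq, config.sfffq)
    instrument_scores: dict[str, object] = {
        "mental_health": mental,
        "physical_activity": activity,
        "diet": diet,
    }

    # physical domain: 9 banded factors through the scoreboard
    from .physical import aggregate_scoreboard

    physical_bands = band_all_factors(profile, config)
    domain_scores: dict[str, DomainScore] = {
        "physical_health": aggregate_scoreboard(physical_bands, config, "physical_health"),
        "mental_health": _instrument_domain_score(mental.domain_band, "mental_health", config),
        "diet": _instrument_domain_score(diet.domain_band, "diet", config),
        "physical_activity": _instrument_domain_score(
            activity.domain_band, "physical_activity", config
        ),
    }
    factor_bands: dict[str, RiskBand] = dict(physical_bands)
    factor_bands["mental_health"] = RiskBand("mental_health", mental.domain_band)
    factor_bands["diet"] = RiskBand("diet", diet.domain_band)
    factor_bands["physical_activity"] = RiskBand("physical_activity", activity.domain_band)

    if frail_required:
        frailty = score_frail(responses.frail, config.frail)
        instrument_scores["frailty"] = frailty
        domain_scores["frailty"] = _instrument_domain_score(
            frailty.domain_band, "frailty", config
        )
        factor_bands["frailty"] = RiskBand("frailty", frailty.domain_band)

    weights = effective_weights(
        profile.age, WeightVector(config.domain_weights), config.frailty_min_age
    )
    composite = composite_score({d: s.raw for d, s in domain_scores.items()}, weights)
    category = categorize(composite, config)
    advice = generate_advice(factor_bands, config, locale)

    applicable = len(physical_bands) + (4 if frail_required else 3)
    scored = sum(1 for rb in factor_bands.values() if not rb.missing)
    return HealthIndexResult(
        composite=composite,
        composite_rounded=round_half_up(composite),
        category=category,
        domain_scores=domain_scores,
        factor_bands=factor_bands,
        instrument_scores=instrument_scores,
        advice=advice,
        completeness=scored / applicable,
        config_digest=config.digest(),
        package_version=__version__,
    )
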