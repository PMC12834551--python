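"""Scoring engines for the four validated questionnaires.

Each scorer takes raw item responses, applies the instrument's published
scoring protocol (kept in :class:`~healthindex.config.ScoringConfig` so
divergent dialects can be configured), and maps the instrument result onto
the shared three-level domain risk band (low / moderate / high).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .config import Dass21Policy, FrailPolicy, IpaqPolicy, RiskLevel, SfffqPolicy
from .errors import InputValidationError

# ---------------------------------------------------------------------------
# DASS-21
# ---------------------------------------------------------------------------

#: 1-based item numbers of each DASS-21 subscale (published assignment).
DASS_DEPRESSION_ITEMS = (3, 5, 10, 13, 16, 17, 21)
DASS_ANXIETY_ITEMS = (2, 4, 7, 9, 15, 19, 20)
DASS_STRESS_ITEMS = (1, 6, 8, 11, 12, 14, 18)

SEVERITY_LEVELS = ("normal", "mild", "moderate", "severe", "extremely_severe")


@dataclass(frozen=True)
class Dass21Responses:
    """The 21 item ratings, each 0-3 (past-week frequency scale)."""

    items: tuple[int, ...]

    def __post_init__(self) -> None:
        items = tuple(self.items)
        object.__setattr__(self, "items", items)
        if len(items) != 21:
            raise InputValidationError(f"DASS-21 requires exactly 21 items, got {len(items)}")
        for i, v in enumerate(items, start=1):
            if not isinstance(v, int) or isinstance(v, bool) or not 0 <= v <= 3:
                raise InputValidationError(f"DASS-21 item {i} must be an integer in 0..3, got {v!r}")


@dataclass(frozen=True)
class MentalHealthScore:
    depression_raw: int
    anxiety_raw: int
    stress_raw: int
    depression_band: str
    anxiety_band: str
    stress_band: str
    domain_band: RiskLevel


def _severity(raw: int, cuts: Sequence[int]) -> str:
    for bound, label in zip(cuts, SEVERITY_LEVELS):
        if raw <= bound:
            return label
    return SEVERITY_LEVELS[-1]


def score_dass21(responses: Dass21Responses, policy: Dass21Policy | None = None) -> MentalHealthScore:
    """Score the DASS-21: subscale raw = 2 x sum of its seven items.

    Severity bands follow the published tables (configurable); the domain
    risk band follows the configured severity -> risk policy (default: any
    severe or extremely severe subscale -> high, any non-normal -> moderate).
    """
    policy = policy or Dass21Policy()
    items = responses.items
    dep = 2 * sum(items[i - 1] for i in DASS_DEPRESSION_ITEMS)
    anx = 2 * sum(items[i - 1] for i in DASS_ANXIETY_ITEMS)
    stress = 2 * sum(items[i - 1] for i in DASS_STRESS_ITEMS)
    bands = (
        _severity(dep, policy.depression_cuts),
        _severity(anx, policy.anxiety_cuts),
        _severity(stress, policy.stress_cuts),
    )
    high_floor = SEVERITY_LEVELS.index(policy.high_if_at_least)
    moderate_floor = SEVERITY_LEVELS.index(policy.moderate_if_at_least)
    ranks = [SEVERITY_LEVELS.index(b) for b in bands]
    if max(ranks) >= high_floor:
        domain = RiskLevel.high
    elif max(ranks) >= moderate_floor:
        domain = RiskLevel.moderate
    else:
        domain = RiskLevel.low
    return MentalHealthScore(dep, anx, stress, bands[0], bands[1], bands[2], domain)


# ---------------------------------------------------------------------------
# IPAQ-SF
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IpaqResponses:
    """Last-7-days activity: days per week and usual minutes per day."""

    vigorous_days: int = 0
    vigorous_min_per_day: float = 0.0
    moderate_days: int = 0
    moderate_min_per_day: float = 0.0
    walking_days: int = 0
    walking_min_per_day: float = 0.0
    sitting_min_per_day: float = 0.0

    def __post_init__(self) -> None:
        for name in ("vigorous_days", "moderate_days", "walking_days"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool) or not 0 <= v <= 7:
                raise InputValidationError(f"IPAQ {name} must be an integer in 0..7, got {v!r}")
        for name in (
            "vigorous_min_per_day",
            "moderate_min_per_day",
            "walking_min_per_day",
            "sitting_min_per_day",
        ):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or isinstance(v, bool) or v < 0:
                raise InputValidationError(f"IPAQ {name} must be non-negative, got {v!r}")


@dataclass(frozen=True)
class PhysicalActivityScore:
    met_min_week: float
    category: str  # low / moderate / high activity
    domain_band: RiskLevel


def _process_minutes(minutes: float, policy: IpaqPolicy) -> float:
    """Published cleaning: <10 min/day recoded to 0; >180 truncated to 180."""
    if minutes < policy.daily_min_floor:
        return 0.0
    return min(minutes, policy.daily_min_cap)


def score_ipaq_sf(responses: IpaqResponses, policy: IpaqPolicy | None = None) -> PhysicalActivityScore:
    """Score the IPAQ short form in MET-minutes/week and categorize.

    MET-min/week = 8.0*vig + 4.0*mod + 3.3*walk over (days x cleaned
    min/day). Categories follow the published rules:

    * high — vigorous on >=3 days reaching >=1500 MET-min/week, or any
      combination on >=7 days reaching >=3000 MET-min/week;
    * moderate — >=3 days of vigorous activity >=20 min/day, or >=5 days
      of moderate activity and/or walking >=30 min/day, or any combination
      on >=5 days reaching >=600 MET-min/week;
    * low — otherwise.

    High activity maps to low domain risk and vice versa.
    """
    policy = policy or IpaqPolicy()
    vig_min = _process_minutes(responses.vigorous_min_per_day, policy)
    mod_min = _process_minutes(responses.moderate_min_per_day, policy)
    walk_min = _process_minutes(responses.walking_min_per_day, policy)
    vig_days = responses.vigorous_days if vig_min > 0 else 0
    mod_days = responses.moderate_days if mod_min > 0 else 0
    walk_days = responses.walking_days if walk_min > 0 else 0

    met = (
        policy.met_vigorous * vig_days * vig_min
        + policy.met_moderate * mod_days * mod_min
        + policy.met_walking * walk_days * walk_min
    )
    total_days = vig_days + mod_days + walk_days

    if (vig_days >= 3 and policy.met_vigorous * vig_days * vig_min >= 1500) or (
        total_days >= 7 and met >= 3000
    ):
        category = "high"
    elif (
        (vig_days >= 3 and vig_min >= 20)
        or ((mod_days if mod_min >= 30 else 0) + (walk_days if walk_min >= 30 else 0) >= 5)
        or (total_days >= 5 and met >= 600)
    ):
        category = "moderate"
    else:
        category = "low"

    domain = {"high": RiskLevel.low, "moderate": RiskLevel.moderate, "low": RiskLevel.high}[category]
    return PhysicalActivityScore(met_min_week=met, category=category, domain_band=domain)


# ---------------------------------------------------------------------------
# SFFFQ diet quality
# ---------------------------------------------------------------------------

SFFFQ_COMPONENTS = ("fruit", "vegetables", "oily_fish", "non_milk_sugar", "fat")


@dataclass(frozen=True)
class SfffqResponses:
    """Ordinal intake-frequency ratings for the five scored food groups.

    The default scale has six levels: 0 never/rarely, 1 less than once a
    week, 2 once a week, 3 two-three times a week, 4 four-six times a week,
    5 daily or more.
    """

    fruit: int
    vegetables: int
    oily_fish: int
    non_milk_sugar: int
    fat: int

    def __post_init__(self) -> None:
        for name in SFFFQ_COMPONENTS:
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool) or v < 0:
                raise InputValidationError(
                    f"SFFFQ frequency for {name!r} must be a non-negative integer, got {v!r}"
                )


@dataclass(frozen=True)
class DietScore:
    component_scores: dict[str, int]
    dqs: int
    domain_band: RiskLevel


def score_sfffq(responses: SfffqResponses, policy: SfffqPolicy | None = None) -> DietScore:
    """Diet quality score: five components each 1-3, DQS = their sum (5-15)."""
    policy = policy or SfffqPolicy()
    components: dict[str, int] = {}
    for name in SFFFQ_COMPONENTS:
        table = getattr(policy, name)
        freq = getattr(responses, name)
        if freq >= len(table):
            raise InputValidationError(
                f"SFFFQ frequency for {name!r} out of range: {freq} (scale has {len(table)} levels)"
            )
        components[name] = table[freq]
    dqs = sum(components.values())
    if dqs >= policy.low_min_dqs:
        band = RiskLevel.low
    elif dqs >= policy.moderate_min_dqs:
        band = RiskLevel.moderate
    else:
        band = RiskLevel.high
    return DietScore(component_scores=components, dqs=dqs, domain_band=band)


# ---------------------------------------------------------------------------
# FRAIL scale
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrailResponses:
    """Fatigue, Resistance, Ambulation, Illnesses count, Loss of weight."""

    fatigue: bool
    resistance: bool
    ambulation: bool
    illnesses_count: int
    weight_loss_over_5pct: bool
    _max_illnesses: int = field(default=11, repr=False, compare=False)

    def __post_init__(self) -> None:
        c = self.illnesses_count
        if not isinstance(c, int) or isinstance(c, bool) or c < 0:
            raise InputValidationError(f"illnesses_count must be a non-negative integer, got {c!r}")
        if c > self._max_illnesses:
            raise InputValidationError(
                f"illnesses_count {c} exceeds the instrument's illness list ({self._max_illnesses})"
            )


@dataclass(frozen=True)
class FrailtyScore:
    score: int
    band: str  # robust / prefrail / frail
    domain_band: RiskLevel


def score_frail(responses: FrailResponses, policy: FrailPolicy | None = None) -> FrailtyScore:
    """FRAIL scale: score = count of positive components (0-5).

    The illnesses component is positive when the count exceeds the
    configured threshold. Bands: 0 robust, 1-2 pre-frail, 3-5 frail.
    """
    policy = policy or FrailPolicy()
    score = (
        int(responses.fatigue)
        + int(responses.resistance)
        + int(responses.ambulation)
        + int(responses.illnesses_count > policy.illness_threshold)
        + int(responses.weight_loss_over_5pct)
    )
    if score == 0:
        band, domain = "robust", RiskLevel.low
    elif score <= 2:
        band, domain = "prefrail", RiskLevel.moderate
    else:
        band, domain = "frail", RiskLevel.high
    return FrailtyScore(score=score, band=band, domain_band=domain)
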