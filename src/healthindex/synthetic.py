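"""Reproducible synthetic respondents, questionnaire answers and outcomes.

The generator draws a latent risk band for every factor from configurable
prevalences, then samples numeric values strictly inside that band's value
range and back-solves questionnaire item vectors that attain the latent
instrument band. By construction the bander and the generator are inverse
on band membership, so assessing a generated record recovers every latent
band exactly — which is what makes the generator a usable test bed.

Healthcare use is simulated per assessed category as over-dispersed
(negative-binomial) counts of NCD-related outpatient visits per year.

Records are generated from per-record random streams keyed by
``(seed, index)``: the same seed gives bit-identical records, and growing
``n`` extends the cohort without reshuffling earlier records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .composite import HealthIndexResult, InstrumentResponses, assess
from .config import ALL_FACTORS, Category, RiskLevel, ScoringConfig
from .errors import ConfigError, InputValidationError
from .instruments import (
    Dass21Responses,
    DASS_ANXIETY_ITEMS,
    DASS_DEPRESSION_ITEMS,
    DASS_STRESS_ITEMS,
    FrailResponses,
    IpaqResponses,
    SFFFQ_COMPONENTS,
    SfffqResponses,
)
from .physical import FamilyHistory, MedicalHistory, RespondentProfile

_BANDS = (RiskLevel.low, RiskLevel.moderate, RiskLevel.high)


class VisitModel(BaseModel):
    """Per-category yearly NCD outpatient-visit distribution (negative
    binomial with the given means and dispersion; dispersion -> inf would be
    Poisson, 1.0 is strongly over-dispersed, typical of visit counts)."""

    model_config = ConfigDict(extra="forbid")

    means: dict[str, float] = Field(
        default_factory=lambda: {"healthy": 0.5, "at_risk": 1.5, "poor_health": 4.0}
    )
    dispersion: float = 1.0

    @model_validator(mode="after")
    def _valid(self) -> "VisitModel":
        if set(self.means) != {c.value for c in Category}:
            raise ValueError(f"visit means must cover categories {[c.value for c in Category]}")
        if any(m < 0 for m in self.means.values()):
            raise ValueError("visit means must be non-negative")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        return self


def _default_prevalences() -> dict[str, dict[str, float]]:
    prev = {f: {"low": 0.6, "moderate": 0.3, "high": 0.1} for f in ALL_FACTORS}
    # family history has no reachable high band (none -> low, any flag -> moderate)
    prev["family_history"] = {"low": 0.7, "moderate": 0.3, "high": 0.0}
    return prev


class CohortConfig(BaseModel):
    """Study conditions for the synthetic cohort.

    Defaults emulate an adult mHealth population: lognormal age with median
    45 y and IQR about 36-58, 53% female, and per-factor band prevalences
    that make the at-risk category dominant.
    """

    model_config = ConfigDict(extra="forbid")

    n: int = Field(default=1200, ge=1)
    seed: int = 0
    age_median: float = 45.0
    age_log_sigma: float = 0.354  # ~ IQR 36-58 around median 45
    age_min: float = 18.0
    age_max: float = 95.0
    sex_female_fraction: float = Field(default=0.53, ge=0.0, le=1.0)
    band_prevalences: dict[str, dict[str, float]] = Field(default_factory=_default_prevalences)
    visit_model: VisitModel = Field(default_factory=VisitModel)

    @model_validator(mode="after")
    def _valid(self) -> "CohortConfig":
        for factor, probs in self.band_prevalences.items():
            if factor not in ALL_FACTORS:
                raise ValueError(f"unknown factor in band_prevalences: {factor!r}")
            if set(probs) - {"low", "moderate", "high"}:
                raise ValueError(f"bad band keys for {factor!r}")
            vals = [probs.get(b.value, 0.0) for b in _BANDS]
            if any(p < 0 or p > 1 for p in vals):
                raise ValueError(f"prevalences for {factor!r} must be in [0, 1]")
            if abs(sum(vals) - 1.0) > 1e-9:
                raise ValueError(f"prevalences for {factor!r} must sum to 1")
        if not self.age_min < self.age_median < self.age_max:
            raise ValueError("age_median must lie inside (age_min, age_max)")
        return self


@dataclass
class SyntheticRecord:
    profile: RespondentProfile
    responses: InstrumentResponses
    true_bands: dict[str, RiskLevel]
    category: Optional[Category] = None  # filled by assess_cohort
    ncd_visits: Optional[int] = None  # filled by simulate_healthcare_use


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _record_rng(seed: int, index: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, index, stream]))


def _draw_band(rng: np.random.Generator, probs: dict[str, float], factor: str) -> RiskLevel:
    p = [probs.get(b.value, 0.0) for b in _BANDS]
    if factor == "family_history" and p[2] > 0:
        raise ConfigError(
            "family_history has no attainable 'high' band under the default band table"
        )
    idx = rng.choice(3, p=p)
    return _BANDS[idx]


def _distribute(rng: np.random.Generator, total: int, n_items: int, max_per_item: int) -> list[int]:
    """Random composition of `total` over `n_items` slots, each 0..max_per_item."""
    if total > n_items * max_per_item:
        raise ValueError("total exceeds capacity")
    slots = [0] * n_items
    for _ in range(total):
        open_slots = [i for i in range(n_items) if slots[i] < max_per_item]
        slots[open_slots[int(rng.integers(len(open_slots)))]] += 1
    return slots


def _uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(rng.uniform(lo, hi))


# ---------------------------------------------------------------------------
# per-factor value samplers (values strictly inside the latent band's range)
# ---------------------------------------------------------------------------


def _sample_bmi(rng: np.random.Generator, band: RiskLevel) -> float:
    if band is RiskLevel.low:
        return _uniform(rng, 18.6, 24.8)
    if band is RiskLevel.moderate:
        # mostly overweight, occasionally underweight
        if rng.random() < 0.88:
            return _uniform(rng, 25.1, 29.8)
        return _uniform(rng, 16.0, 18.3)
    return _uniform(rng, 30.2, 42.0)


def _sample_waist(rng: np.random.Generator, band: RiskLevel, sex: str) -> float:
    if sex == "male":
        ranges = {"low": (76.0, 93.0), "moderate": (94.5, 101.0), "high": (102.5, 125.0)}
    else:
        ranges = {"low": (64.0, 79.0), "moderate": (80.5, 87.0), "high": (88.5, 115.0)}
    return _uniform(rng, *ranges[band.value])


def _sample_bp(rng: np.random.Generator, band: RiskLevel) -> tuple[float, float]:
    if band is RiskLevel.low:
        return _uniform(rng, 98.0, 119.0), _uniform(rng, 60.0, 79.0)
    if band is RiskLevel.moderate:
        return _uniform(rng, 120.5, 139.0), _uniform(rng, 68.0, 79.0)
    return _uniform(rng, 140.5, 175.0), _uniform(rng, 90.5, 105.0)


def _sample_ldl(rng: np.random.Generator, band: RiskLevel) -> float:
    ranges = {"low": (1.3, 2.55), "moderate": (2.65, 4.05), "high": (4.2, 6.2)}
    return _uniform(rng, *ranges[band.value])


def _sample_glycaemia(rng: np.random.Generator, band: RiskLevel) -> tuple[float, float]:
    fbg_ranges = {"low": (4.2, 5.5), "moderate": (5.65, 6.85), "high": (7.1, 11.0)}
    hba1c_ranges = {"low": (4.8, 5.6), "moderate": (5.75, 6.4), "high": (6.6, 10.5)}
    return _uniform(rng, *fbg_ranges[band.value]), _uniform(rng, *hba1c_ranges[band.value])


def _sample_alcohol(
    rng: np.random.Generator, band: RiskLevel, sex: str, config: ScoringConfig
) -> tuple[bool, Optional[float]]:
    limit = (
        config.alcohol_limits.weekly_male if sex == "male" else config.alcohol_limits.weekly_female
    )
    if band is RiskLevel.low:
        return False, None
    if band is RiskLevel.moderate:
        return True, _uniform(rng, 0.5, limit)
    return True, _uniform(rng, limit + 0.5, limit + 14.0)


# ---------------------------------------------------------------------------
# questionnaire back-solvers
# ---------------------------------------------------------------------------


def _dass_items_for_band(rng: np.random.Generator, band: RiskLevel) -> Dass21Responses:
    """Construct a 21-item vector whose subscale severities yield the target
    mental-health domain band under the default severity -> risk policy."""
    # subscale sums (raw = 2*sum): normal ceilings dep<=4, anx<=3, stress<=7
    dep_sum = int(rng.integers(0, 5))
    anx_sum = int(rng.integers(0, 4))
    stress_sum = int(rng.integers(0, 8))
    if band is not RiskLevel.low:
        which = int(rng.integers(3))
        if band is RiskLevel.moderate:
            # mild..moderate severity, none severe
            if which == 0:
                dep_sum = int(rng.integers(5, 11))  # raw 10..20
            elif which == 1:
                anx_sum = int(rng.integers(4, 8))  # raw 8..14
            else:
                stress_sum = int(rng.integers(8, 13))  # raw 16..24 (mild..moderate)
        else:
            # severe or extremely severe on one subscale
            if which == 0:
                dep_sum = int(rng.integers(11, 22))  # raw 22..42
            elif which == 1:
                anx_sum = int(rng.integers(8, 22))  # raw 16..42
            else:
                stress_sum = int(rng.integers(13, 22))  # raw 26..42
    items = [0] * 21
    for one_based, count in (
        (DASS_DEPRESSION_ITEMS, dep_sum),
        (DASS_ANXIETY_ITEMS, anx_sum),
        (DASS_STRESS_ITEMS, stress_sum),
    ):
        vals = _distribute(rng, count, 7, 3)
        for pos, v in zip(one_based, vals):
            items[pos - 1] = v
    return Dass21Responses(items=tuple(items))


def _ipaq_for_band(rng: np.random.Generator, band: RiskLevel) -> IpaqResponses:
    sitting = float(rng.integers(180, 600))
    if band is RiskLevel.low:  # high activity
        days = int(rng.integers(3, 8))
        min_needed = int(np.ceil(1500.0 / (8.0 * days))) + 1
        minutes = float(rng.integers(min_needed, 181))
        return IpaqResponses(
            vigorous_days=days, vigorous_min_per_day=minutes, sitting_min_per_day=sitting
        )
    if band is RiskLevel.moderate:
        days = int(rng.integers(5, 8))
        minutes = float(rng.integers(30, 61))
        return IpaqResponses(
            walking_days=days, walking_min_per_day=minutes, sitting_min_per_day=sitting
        )
    # low activity: at most 2 short walking days
    days = int(rng.integers(0, 3))
    minutes = float(rng.integers(0, 26)) if days else 0.0
    return IpaqResponses(
        walking_days=days, walking_min_per_day=minutes, sitting_min_per_day=sitting
    )


def _sfffq_for_band(
    rng: np.random.Generator, band: RiskLevel, config: ScoringConfig
) -> SfffqResponses:
    policy = config.sfffq
    if band is RiskLevel.low:
        dqs = int(rng.integers(policy.low_min_dqs, 16))
    elif band is RiskLevel.moderate:
        dqs = int(rng.integers(policy.moderate_min_dqs, policy.low_min_dqs))
    else:
        dqs = int(rng.integers(5, policy.moderate_min_dqs))
    comps = [c + 1 for c in _distribute(rng, dqs - 5, 5, 2)]  # each 1..3, sum = dqs
    freqs = {}
    for name, score in zip(SFFFQ_COMPONENTS, comps):
        table = getattr(policy, name)
        candidates = [i for i, s in enumerate(table) if s == score]
        freqs[name] = candidates[int(rng.integers(len(candidates)))]
    return SfffqResponses(**freqs)


def _frail_for_band(
    rng: np.random.Generator, band: RiskLevel, config: ScoringConfig
) -> FrailResponses:
    if band is RiskLevel.low:
        count = 0
    elif band is RiskLevel.moderate:
        count = int(rng.integers(1, 3))
    else:
        count = int(rng.integers(3, 6))
    positives = rng.permutation(5)[:count]
    comp = [i in positives for i in range(5)]
    thr = config.frail.illness_threshold
    max_ill = config.frail.illness_list_length
    illnesses = int(rng.integers(thr + 1, max_ill + 1)) if comp[3] else int(rng.integers(0, thr + 1))
    return FrailResponses(
        fatigue=comp[0],
        resistance=comp[1],
        ambulation=comp[2],
        illnesses_count=illnesses,
        weight_loss_over_5pct=comp[4],
    )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def generate_record(
    config: CohortConfig, index: int, scoring: ScoringConfig | None = None
) -> SyntheticRecord:
    """Generate the `index`-th record of the cohort (stream-stable)."""
    scoring = scoring or ScoringConfig()
    rng = _record_rng(config.seed, index, stream=0)

    age = round(
        float(
            np.clip(
                np.exp(np.log(config.age_median) + config.age_log_sigma * rng.standard_normal()),
                config.age_min,
                config.age_max,
            )
        ),
        1,
    )
    sex = "female" if rng.random() < config.sex_female_fraction else "male"
    has_frail = age >= scoring.frailty_min_age

    bands: dict[str, RiskLevel] = {}
    for factor in ALL_FACTORS:
        if factor == "frailty" and not has_frail:
            continue
        probs = config.band_prevalences.get(factor, {"low": 1.0, "moderate": 0.0, "high": 0.0})
        bands[factor] = _draw_band(rng, probs, factor)

    bmi = _sample_bmi(rng, bands["bmi"])
    height = float(np.clip(rng.normal(170.0 if sex == "male" else 158.0, 7.0), 145.0, 195.0))
    weight = round(bmi * (height / 100.0) ** 2, 2)
    sbp, dbp = _sample_bp(rng, bands["blood_pressure"])
    fbg, hba1c = _sample_glycaemia(rng, bands["glycaemia"])
    drinks, drinks_per_week = _sample_alcohol(rng, bands["alcohol"], sex, scoring)
    fh = FamilyHistory() if bands["family_history"] is RiskLevel.low else FamilyHistory(
        **{
            ("diabetes", "premature_cvd", "familial_hyperlipidemia")[int(rng.integers(3))]: True
        }
    )
    mh_band = bands["medical_history"]
    if mh_band is RiskLevel.low:
        mh = MedicalHistory()
    elif mh_band is RiskLevel.moderate:
        mh = MedicalHistory(unsure=True)
    else:
        mh = MedicalHistory(
            **{("cvd", "cerebrovascular", "cancer", "hypertension", "diabetes")[int(rng.integers(5))]: True}
        )

    profile = RespondentProfile(
        age=age,
        sex=sex,
        ethnicity=("malay", "chinese", "other")[int(rng.choice(3, p=[0.83, 0.11, 0.06]))],
        height=round(height, 1),
        weight=weight,
        waist=round(_sample_waist(rng, bands["waist"], sex), 1),
        smoking={"low": "never", "moderate": "former", "high": "current"}[
            bands["smoking"].value
        ],
        drinks_alcohol=drinks,
        std_drinks_per_week=None if drinks_per_week is None else round(drinks_per_week, 1),
        family_history=fh,
        medical_history=mh,
        sbp=round(sbp, 1),
        dbp=round(dbp, 1),
        ldl=round(_sample_ldl(rng, bands["ldl"]), 2),
        fbg=round(fbg, 2),
        hba1c=round(hba1c, 2),
    )
    responses = InstrumentResponses(
        dass21=_dass_items_for_band(rng, bands["mental_health"]),
        ipaq_sf=_ipaq_for_band(rng, bands["physical_activity"]),
        sfffq=_sfffq_for_band(rng, bands["diet"], scoring),
        frail=_frail_for_band(rng, bands["frailty"], scoring) if has_frail else None,
    )
    return SyntheticRecord(profile=profile, responses=responses, true_bands=bands)


def generate_cohort(
    config: CohortConfig, scoring: ScoringConfig | None = None
) -> list[SyntheticRecord]:
    """Generate `config.n` records. Same (config, seed) -> identical cohort;
    increasing only `n` extends the cohort without changing earlier records."""
    scoring = scoring or ScoringConfig()
    return [generate_record(config, i, scoring) for i in range(config.n)]


def assess_cohort(
    records: Sequence[SyntheticRecord], scoring: ScoringConfig | None = None
) -> list[HealthIndexResult]:
    """Assess every record, filling in each record's category."""
    scoring = scoring or ScoringConfig()
    results = []
    for rec in records:
        res = assess(rec.profile, rec.responses, scoring)
        rec.category = res.category
        results.append(res)
    return results


def simulate_healthcare_use(
    records: Sequence[SyntheticRecord],
    visit_model: VisitModel | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Draw yearly NCD-related outpatient-visit counts per assessed record.

    Counts are negative binomial with the category's configured mean and the
    model's dispersion; a zero mean yields all-zero counts. Each record draws
    from its own ``(seed, index)`` stream, so the vector is reproducible and
    extension-stable. Records must have been assessed first.
    """
    visit_model = visit_model or VisitModel()
    k = visit_model.dispersion
    visits = np.zeros(len(records), dtype=int)
    for i, rec in enumerate(records):
        if rec.category is None:
            raise InputValidationError(
                f"record {i} has no category; run assess_cohort before simulating use"
            )
        try:
            mu = visit_model.means[rec.category.value]
        except KeyError:
            raise InputValidationError(f"unknown category {rec.category!r}") from None
        if mu == 0:
            visits[i] = 0
            continue
        rng = _record_rng(seed, i, stream=1)
        visits[i] = int(rng.negative_binomial(k, k / (k + mu)))
        rec.ncd_visits = int(visits[i])
    return visits
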