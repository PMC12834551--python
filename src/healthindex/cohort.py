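"""Planned validation analytics over (score, category, outcome) data.

Implements the statistics the score is meant to be validated with against
healthcare-use outcomes: category summaries and domain concern ranking,
ANOVA / Kruskal-Wallis comparison of visit counts across categories,
chi-square on category x morbidity tables, Pearson correlation of raw score
with use, ROC analysis of the score's discriminative ability, and the
one-way-ANOVA sample-size computation (noncentral F, lambda = f^2 * N).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .composite import HealthIndexResult
from .config import Category, RiskLevel, ScoringConfig
from .errors import InputValidationError

CATEGORY_ORDER = (Category.healthy, Category.at_risk, Category.poor_health)


@dataclass(frozen=True)
class CohortSummary:
    n_total: int
    n_per_category: dict[str, int]
    pct_per_category: dict[str, float]
    median_age: float
    age_iqr: tuple[float, float]
    fraction_female: float
    domain_concern: dict[str, float]  # fraction banded moderate-or-high, per factor
    concern_ranking: list[str]  # factors sorted by concern, descending


@dataclass(frozen=True)
class GroupTestResult:
    method: str  # "anova" | "kruskal_wallis"
    statistic: float
    p_value: float


@dataclass(frozen=True)
class ChisqResult:
    statistic: float
    dof: int
    p_value: float


@dataclass(frozen=True)
class PearsonResult:
    r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class RocResult:
    auc: float
    # (threshold on the displayed 0-100 scale, sensitivity, specificity)
    at_poor_cutoff: tuple[float, float, float]
    at_healthy_cutoff: tuple[float, float, float]
    youden: tuple[float, float, float]


@dataclass(frozen=True)
class ValidationReport:
    summary: CohortSummary
    group_test: GroupTestResult
    chisq: Optional[ChisqResult]
    pearson: PearsonResult
    roc: Optional[RocResult]


def summarize_categories(
    results: Sequence[HealthIndexResult],
    ages: Optional[Sequence[float]] = None,
    sexes: Optional[Sequence[str]] = None,
    config: ScoringConfig | None = None,
) -> CohortSummary:
    """Counts and percentages per category plus the domain concern ranking.

    Concern = fraction of respondents whose factor is banded moderate or
    high; ties are broken by config factor order.
    """
    config = config or ScoringConfig()
    if not results:
        raise InputValidationError("cannot summarize an empty cohort")
    n = len(results)
    counts = {c.value: 0 for c in CATEGORY_ORDER}
    for r in results:
        counts[r.category.value] += 1
    pcts = {c: round(100.0 * k / n, 1) for c, k in counts.items()}

    concern: dict[str, float] = {}
    for factor in config.factors:
        flagged = sum(
            1
            for r in results
            if factor in r.factor_bands
            and not r.factor_bands[factor].missing
            and r.factor_bands[factor].band in (RiskLevel.moderate, RiskLevel.high)
        )
        denom = sum(1 for r in results if factor in r.factor_bands)
        concern[factor] = flagged / denom if denom else 0.0
    order = {f: i for i, f in enumerate(config.factors)}
    ranking = sorted(concern, key=lambda f: (-concern[f], order[f]))

    if ages is not None and len(ages) > 0:
        med = float(np.median(ages))
        iqr = (float(np.percentile(ages, 25)), float(np.percentile(ages, 75)))
    else:
        med, iqr = float("nan"), (float("nan"), float("nan"))
    frac_f = (
        sum(1 for s in sexes if s == "female") / len(sexes) if sexes else float("nan")
    )
    return CohortSummary(
        n_total=n,
        n_per_category=counts,
        pct_per_category=pcts,
        median_age=med,
        age_iqr=iqr,
        fraction_female=frac_f,
        domain_concern=concern,
        concern_ranking=ranking,
    )


def compare_use_across_categories(
    visits_by_category: Mapping[str, Sequence[float]],
    method: str = "kruskal_wallis",
) -> GroupTestResult:
    """One-way ANOVA or Kruskal-Wallis across >= 2 non-empty groups.

    Kruskal-Wallis (tie-corrected) is the default — visit counts are skewed.
    Degenerate all-identical data yields H = 0, p = 1 rather than an error.
    """
    groups = [np.asarray(v, dtype=float) for v in visits_by_category.values() if len(v) > 0]
    if len(groups) < 2:
        raise InputValidationError("need at least two non-empty groups")
    if method == "anova":
        if any(len(g) < 2 for g in groups):
            raise InputValidationError(
                "ANOVA needs >= 2 observations per group; consider method='kruskal_wallis'"
            )
        stat, p = stats.f_oneway(*groups)
    elif method == "kruskal_wallis":
        pooled = np.concatenate(groups)
        if np.all(pooled == pooled[0]):
            return GroupTestResult(method=method, statistic=0.0, p_value=1.0)
        stat, p = stats.kruskal(*groups)
    else:
        raise InputValidationError(f"unknown method {method!r} (anova | kruskal_wallis)")
    return GroupTestResult(method=method, statistic=float(stat), p_value=float(p))


def category_morbidity_chisq(contingency: Sequence[Sequence[int]]) -> ChisqResult:
    """Pearson chi-square on a category x morbidity count table."""
    table = np.asarray(contingency, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise InputValidationError("contingency table must be at least 2x2")
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise InputValidationError("contingency table must hold non-negative integer counts")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise InputValidationError("contingency table has an all-zero row or column")
    stat, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return ChisqResult(statistic=float(stat), dof=int(dof), p_value=float(p))


def score_use_correlation(
    scores: Sequence[float], visits: Sequence[float]
) -> PearsonResult:
    """Pearson correlation between raw composite score and healthcare use."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(visits, dtype=float)
    if len(x) != len(y):
        raise InputValidationError("scores and visits must have equal length")
    if len(x) < 3:
        raise InputValidationError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InputValidationError("zero variance in scores or visits")
    res = stats.pearsonr(x, y)
    return PearsonResult(r=float(res.statistic), p_value=float(res.pvalue), n=len(x))


def _sens_spec_at(scores: np.ndarray, labels: np.ndarray, cutoff: float) -> tuple[float, float, float]:
    """Sensitivity/specificity when 'score <= cutoff' predicts disease."""
    pred = scores <= cutoff
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return (float(cutoff), sens, spec)


def roc_analysis(
    scores: Sequence[float],
    ncd_flag: Sequence[int],
    low_score_predicts_disease: bool = True,
    config: ScoringConfig | None = None,
) -> RocResult:
    """ROC of the composite score against an NCD outcome flag.

    A *low* Health Index indicates higher risk, so scores are negated before
    the standard (higher-predicts-positive) AUC computation by default.
    Sensitivity/specificity are reported at the two category cutoffs and at
    the Youden-optimal threshold.
    """
    config = config or ScoringConfig()
    s = np.asarray(scores, dtype=float)
    y = np.asarray(ncd_flag, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise InputValidationError("ncd_flag must contain both classes (0 and 1)")
    oriented = -s if low_score_predicts_disease else s
    auc = float(roc_auc_score(y, oriented))
    fpr, tpr, thr = roc_curve(y, oriented)
    youden_idx = int(np.argmax(tpr - fpr))
    youden_cutoff = float(-thr[youden_idx] if low_score_predicts_disease else thr[youden_idx])
    display = s if low_score_predicts_disease else s  # cutoffs live on the 0-100 scale
    _, ysens, yspec = _sens_spec_at(display, y, youden_cutoff)
    return RocResult(
        auc=auc,
        at_poor_cutoff=_sens_spec_at(display, y, float(config.thresholds.poor_max)),
        at_healthy_cutoff=_sens_spec_at(display, y, float(config.thresholds.at_risk_max)),
        youden=(youden_cutoff, ysens, yspec),
    )


def anova_power(n_per_group: int, effect_size_f: float, alpha: float, groups: int) -> float:
    """Power of one-way ANOVA with noncentrality lambda = f^2 * N."""
    n_total = n_per_group * groups
    df1 = groups - 1
    df2 = n_total - groups
    if df2 < 1:
        return 0.0
    nc = effect_size_f**2 * n_total
    fcrit = stats.f.isf(alpha, df1, df2)
    return float(stats.ncf.sf(fcrit, df1, df2, nc))


def required_sample_size(
    effect_size_f: float, alpha: float = 0.05, power: float = 0.80, groups: int = 3
) -> int:
    """Smallest per-group n whose one-way-ANOVA power reaches the target.

    Monotone: decreasing in f, increasing in the power target.
    """
    if effect_size_f <= 0:
        raise InputValidationError("effect size f must be positive")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise InputValidationError("alpha and power must lie in (0, 1)")
    if groups < 2:
        raise InputValidationError("need at least 2 groups")
    for n in range(2, 1_000_000):
        if anova_power(n, effect_size_f, alpha, groups) >= power:
            return n
    raise InputValidationError("parameters infeasible within n <= 1e6 per group")


def visits_by_category(
    categories: Sequence[Category | str], visits: Sequence[float]
) -> dict[str, list[float]]:
    """Group a visit vector by category label, in canonical category order."""
    if len(categories) != len(visits):
        raise InputValidationError("categories and visits must have equal length")
    out: dict[str, list[float]] = {c.value: [] for c in CATEGORY_ORDER}
    for c, v in zip(categories, visits):
        key = c.value if isinstance(c, Category) else str(c)
        if key not in out:
            raise InputValidationError(f"unknown category {c!r}")
        out[key].append(float(v))
    return {k: v for k, v in out.items() if v}


def stratified(test, strata: Sequence[object], *columns: Sequence, **kwargs):
    """Group-by wrapper for confounder control (age bands, sex, ...).

    Runs ``test(*columns_restricted_to_stratum, **kwargs)`` for every
    distinct stratum value; a stratum whose data fail the test's
    preconditions gets the raised error in its slot instead of a result.
    """
    out: dict[object, object] = {}
    for value in sorted(set(strata), key=str):
        mask = [s == value for s in strata]
        sliced = [[x for x, m in zip(col, mask) if m] for col in columns]
        try:
            out[value] = test(*sliced, **kwargs)
        except InputValidationError as exc:
            out[value] = exc
    return out
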