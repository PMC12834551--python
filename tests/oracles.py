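"""Independently coded brute-force oracles for the questionnaire scorers and
validation statistics.

Everything here is written from the published rule tables directly, without
importing scoring logic from the package, so scorer and oracle are two
independent encodings of the same rules.
"""

from __future__ import annotations

import math

# --- DASS-21: item -> subscale assignment written out item by item ---------

_DASS_SUBSCALE_BY_ITEM = {
    1: "s", 2: "a", 3: "d", 4: "a", 5: "d", 6: "s", 7: "a",
    8: "s", 9: "a", 10: "d", 11: "s", 12: "s", 13: "d", 14: "s",
    15: "a", 16: "d", 17: "d", 18: "s", 19: "a", 20: "a", 21: "d",
}


def dass21_subscale_raws(items):
    """(depression, anxiety, stress) raw = doubled sum of assigned items."""
    sums = {"d": 0, "a": 0, "s": 0}
    for idx, value in enumerate(items, start=1):
        sums[_DASS_SUBSCALE_BY_ITEM[idx]] += value
    return 2 * sums["d"], 2 * sums["a"], 2 * sums["s"]


def dass21_severity(subscale: str, raw: int) -> str:
    tables = {
        "depression": [(9, "normal"), (13, "mild"), (20, "moderate"), (27, "severe")],
        "anxiety": [(7, "normal"), (9, "mild"), (14, "moderate"), (19, "severe")],
        "stress": [(14, "normal"), (18, "mild"), (25, "moderate"), (33, "severe")],
    }
    for bound, label in tables[subscale]:
        if raw <= bound:
            return label
    return "extremely_severe"


# --- IPAQ-SF ----------------------------------------------------------------


def ipaq_met_minutes(vd, vm, md, mm, wd, wm):
    """MET-min/week after the 10-min floor and 180-min cap, written afresh."""
    def clean(m):
        if m < 10:
            return 0.0
        return 180.0 if m > 180 else float(m)

    vm, mm, wm = clean(vm), clean(mm), clean(wm)
    return 8.0 * vd * vm + 4.0 * mm * md + 3.3 * wd * wm


def ipaq_category(vd, vm, md, mm, wd, wm):
    def clean(m):
        if m < 10:
            return 0.0
        return 180.0 if m > 180 else float(m)

    vm, mm, wm = clean(vm), clean(mm), clean(wm)
    vd = vd if vm else 0
    md = md if mm else 0
    wd = wd if wm else 0
    met = 8.0 * vd * vm + 4.0 * md * mm + 3.3 * wd * wm
    days = vd + md + wd
    if (vd >= 3 and 8.0 * vd * vm >= 1500) or (days >= 7 and met >= 3000):
        return "high"
    if (vd >= 3 and vm >= 20):
        return "moderate"
    if (md if mm >= 30 else 0) + (wd if wm >= 30 else 0) >= 5:
        return "moderate"
    if days >= 5 and met >= 600:
        return "moderate"
    return "low"


# --- SFFFQ ------------------------------------------------------------------

_SFFFQ_TABLES = {
    "fruit": [1, 1, 2, 2, 3, 3],
    "vegetables": [1, 1, 2, 2, 3, 3],
    "oily_fish": [1, 2, 3, 3, 3, 3],
    "non_milk_sugar": [3, 3, 2, 2, 1, 1],
    "fat": [3, 3, 2, 2, 1, 1],
}


def sfffq_dqs(freqs: dict) -> int:
    return sum(_SFFFQ_TABLES[name][freq] for name, freq in freqs.items())


def sfffq_band(dqs: int) -> str:
    if dqs >= 12:
        return "low"
    if dqs >= 8:
        return "moderate"
    return "high"


# --- FRAIL ------------------------------------------------------------------


def frail_score(fatigue, resistance, ambulation, illnesses_count, weight_loss, threshold=5):
    return sum(
        [bool(fatigue), bool(resistance), bool(ambulation), illnesses_count > threshold, bool(weight_loss)]
    )


def frail_band(score: int) -> str:
    return "robust" if score == 0 else ("prefrail" if score <= 2 else "frail")


# --- statistics: brute-force references --------------------------------------


def chisq_by_hand(table):
    """Pearson chi-square via explicit expected counts."""
    rows = len(table)
    cols = len(table[0])
    total = sum(sum(r) for r in table)
    row_sums = [sum(r) for r in table]
    col_sums = [sum(table[i][j] for i in range(rows)) for j in range(cols)]
    stat = 0.0
    for i in range(rows):
        for j in range(cols):
            expected = row_sums[i] * col_sums[j] / total
            stat += (table[i][j] - expected) ** 2 / expected
    return stat, (rows - 1) * (cols - 1)


def auc_by_concordance(scores, labels, low_predicts_disease=True):
    """AUC as the fraction of (diseased, healthy) pairs correctly ordered,
    counting ties as 1/2. 'Correctly ordered' = diseased scored lower when
    low scores predict disease."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if (p < n) if low_predicts_disease else (p > n):
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def kruskal_h_by_hand(groups):
    """Tie-corrected Kruskal-Wallis H from explicit mid-ranks."""
    pooled = sorted((v, gi) for gi, g in enumerate(groups) for v in g)
    n = len(pooled)
    # mid-ranks
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[j + 1][0] == pooled[i][0]:
            j += 1
        mid = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[k] = mid
        i = j + 1
    rank_sums = [0.0] * len(groups)
    counts = [0] * len(groups)
    for (val, gi), r in zip(pooled, ranks):
        rank_sums[gi] += r
        counts[gi] += 1
    h = 12.0 / (n * (n + 1)) * sum(
        rs**2 / c for rs, c in zip(rank_sums, counts)
    ) - 3 * (n + 1)
    # tie correction
    tie_sum = 0
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[j + 1][0] == pooled[i][0]:
            j += 1
        t = j - i + 1
        tie_sum += t**3 - t
        i = j + 1
    correction = 1.0 - tie_sum / float(n**3 - n)
    return h / correction if correction > 0 else 0.0


def pearson_r_by_hand(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)
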