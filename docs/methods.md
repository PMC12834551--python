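# Methods

## The composite score

The Health Index is a weighted sum `HI = Σᵢ Sᵢ·wᵢ` over five domain scores
Sᵢ ∈ [0, 100] with weights wᵢ ≥ 0, Σwᵢ = 1. The shipped defaults are equal
weights (0.2 per domain). Frailty is only assessed from age 60 (inclusive;
the age gate is `frailty_min_age` in config): below that age its weight is
set to 0 and the other weights are divided by their collective sum, which
preserves their proportions and keeps the vector summing to 1 — with equal
base weights each remaining domain gets 0.25.

Domain scores are natively on 0–100, so the min-max normalization step
(`normalize_domain`) is the identity under defaults; it exists for
configurations whose scoreboards emit other ranges (e.g. mapping the DQS
5–15 directly).

### Categorization and rounding

The displayed score is the composite rounded half-up to an integer; the
category is a function of that integer alone: healthy ≥ 82, at risk 31–81,
poor health ≤ 30. Non-integer composites in the open gaps (30, 31) and
(81, 82) therefore resolve by ordinary rounding — 81.5 rounds to 82 and is
healthy, 30.4 rounds to 30 and is poor health. The unrounded composite is
retained on every result for downstream statistics.

These cutoffs are reconstructible from the domain band boundaries: if every
domain sits exactly at its low-risk minimum (82), any weight vector summing
to 1 yields a composite of exactly 82, and likewise 30 for the high-risk
maximum. The property-based tests verify this for random Dirichlet weights.

### The scoreboard

Factor severity bands map to points low → 91, moderate → 56, high → 15 —
the midpoints of the three composite category ranges (82–100, 31–81, 0–30)
— so a profile uniformly banded at one level lands inside the matching
category. The physical-health domain is the weighted mean (equal factor
weights by default) of the points of its nine factors; missing factors
(absent biomarkers without a diagnosis flag) are excluded and the weights
renormalized over the factors that could be scored, with the fraction scored
reported as `completeness`. Exclusion was chosen over imputing "moderate"
because an unmeasured biomarker carries no information either way; the
completeness flag makes reduced accuracy visible downstream. If every
factor is missing the domain is unscorable and assessment fails loudly.

Each questionnaire-backed domain takes the points of its instrument's risk
band directly (so its raw is one of 91/56/15 under defaults).

## Factor band tables (defaults)

- **BMI** (kg/m², WHO): < 18.5 moderate (underweight), 18.5–24.9 low,
  25.0–29.9 moderate (overweight; 29.9 is the largest overweight value),
  ≥ 30.0 high. An `asian_cutoffs` toggle switches to 23/27.5.
- **Waist** (cm, WHO, sex-specific): men ≥ 102 high, 94–101.9 moderate;
  women ≥ 88 high, 80–87.9 moderate; otherwise low.
- **Blood pressure** (mmHg): < 120/80 low; SBP 120–139 or DBP 80–89
  moderate; SBP ≥ 140 or DBP ≥ 90 or diagnosed hypertension high. Both
  readings are required for measurement-based banding; a diagnosis alone
  bands high.
- **LDL** (mmol/L): < 2.6 low, 2.6–4.1 moderate, > 4.1 or diagnosed
  dyslipidemia high.
- **Glycaemia**: fasting glucose and HbA1c proxy the same construct and are
  one factor scored by the worse of the two: FBG < 5.6 / HbA1c < 5.7 low;
  FBG 5.6–6.9 / HbA1c 5.7–6.4 moderate; FBG ≥ 7.0, HbA1c ≥ 6.5 or diagnosed
  type-2 diabetes high.
- **Smoking**: never/former/current → low/moderate/high.
- **Alcohol**: abstinent (or zero weekly drinks) low; within the weekly
  standard-drink limit (14 men / 7 women, the usual daily 2/1 limits as
  weekly totals) moderate; above it high.
- **Family history**: none low, any flag (diabetes, premature CVD, familial
  hyperlipidemia) moderate. There is deliberately no high band — a
  predisposition is not a diagnosis — which also means the end-to-end
  composite floor is 16.1, not 15, since this factor cannot reach 15 points.
- **Medical history**: none low, "unsure" moderate (a policy choice, kept in
  config as `unsure_history_band`), any diagnosed NCD high.

All boundaries are half-open as listed and exhaustively swept in tests.

## Instrument scoring

- **DASS-21**: 21 items rated 0–3; the depression, anxiety and stress
  subscales each own seven fixed items; subscale raw = twice the item sum
  (0–42, always even). Severity cuts (inclusive upper bounds on the raw):
  depression 9/13/20/27, anxiety 7/9/14/19, stress 14/18/25/33 for
  normal/mild/moderate/severe; above is extremely severe. Domain risk
  policy (configurable): any subscale ≥ severe → high; any ≥ mild →
  moderate; else low.
- **IPAQ-SF**: per-activity daily minutes below 10 are recoded to 0 and
  above 180 truncated to 180 before scoring. MET-min/week =
  8.0·vig_days·vig_min + 4.0·mod_days·mod_min + 3.3·walk_days·walk_min.
  Categories: *high* = vigorous on ≥ 3 days totalling ≥ 1500 MET-min, or
  ≥ 7 activity days totalling ≥ 3000 MET-min; *moderate* = ≥ 3 days of
  ≥ 20-min vigorous activity, or ≥ 5 days of ≥ 30-min moderate activity or
  walking, or ≥ 5 activity days totalling ≥ 600 MET-min; else *low*.
  Activity category maps inversely to domain risk.
- **SFFFQ**: each scored food group is answered on a six-level ordinal
  frequency scale (never/rarely, < 1/week, 1/week, 2–3/week, 4–6/week,
  daily+). Config tables map frequency to a 1–3 component score —
  protective groups (fruit, vegetables, oily fish) score up with frequency,
  sugar and fat score down. The diet quality score is the component sum
  (5–15); risk bands at DQS ≥ 12 low, 8–11 moderate, ≤ 7 high. The
  frequency scale and tables are this package's dialect (kept fully in
  config); the component structure and DQS range follow the instrument.
- **FRAIL**: five binary components; the illnesses component is positive
  when the illness count exceeds the configured threshold (default 5 of an
  11-item list). Score 0 robust → low risk, 1–2 pre-frail → moderate,
  3–5 frail → high.

Item-level missingness is rejected everywhere: only fully completed
questionnaires are scored, matching the all-or-nothing completion model the
score assumes.

## Synthetic cohorts

The generator is the package's test bed and defines its study conditions.
Per record it draws a latent band for each factor from configurable
prevalences (default 0.60/0.30/0.10 low/moderate/high per factor; family
history 0.70/0.30/0 because its high band is unreachable), samples numeric
values strictly inside the band's value range with a safety margin against
floating-point boundary effects, and back-solves questionnaire item vectors
that attain the latent instrument band. Generator and bander are therefore
inverse on band membership, and the recovery test asserts exact agreement
on every latent band. Demographics default to a lognormal age (median 45,
log-sd 0.354 ≈ IQR 36–58, clamped to 18–95) and 53% female. With these
defaults the assessed mix is at-risk-dominant (roughly 77% at risk, 22%
healthy, < 1% poor health at n = 1200) — deliberately imbalanced, as an
adult screening population tends to be.

Randomness is stream-stable: record *i* draws from a generator seeded with
`(seed, i)`, so the same seed is bit-reproducible and growing *n* extends a
cohort without reshuffling earlier records.

Healthcare use is simulated per assessed category as negative-binomial
visit counts (means 0.5 / 1.5 / 4.0 for healthy / at risk / poor health,
dispersion 1.0 — over-dispersion is typical of outpatient-visit counts).
A zero mean yields exactly zero counts.

What the generator does **not** emulate: correlated risk factors (bands are
independent across factors), measurement error, item-level answer styles,
missing biomarkers, or any calibration to a real population. Passing tests
therefore demonstrate the engine's correctness and the statistics'
behaviour under known effects — not real-world predictive validity, which
requires field data.

## Validation statistics

- Group comparison of visits across categories: Kruskal-Wallis
  (tie-corrected) by default — counts are skewed — with one-way ANOVA as a
  flag; ANOVA requires ≥ 2 observations per group. All-identical data
  return H = 0, p = 1.
- Chi-square on category × morbidity tables (Pearson, no continuity
  correction, dof = (r−1)(c−1)); zero rows/columns are rejected.
- Pearson correlation of the unrounded composite with visit counts.
- ROC: a *low* score predicts disease, so scores are negated before the
  standard AUC computation; sensitivity/specificity are reported at the two
  category cutoffs (30 and 82, "score ≤ cutoff predicts disease") and at
  the Youden-optimal threshold.
- Sample size: smallest per-group n whose one-way-ANOVA power, computed
  from the noncentral F with noncentrality λ = f²·N, reaches the target.
  For f = 0.3, α = 0.05, power = 0.80, 3 groups this yields 37 per group
  (power 0.792 at 36, 0.803 at 37); G*Power-style outputs may differ by one
  depending on rounding convention.
- `stratified` wraps any of the above per stratum (age band, sex) for
  confounder control.

### Monte-Carlo behaviour and problem sizes

The power check runs the full pipeline (generate → assess → simulate → test)
at n = 600 for 200 seeded replicates; under the default visit model the
Kruskal-Wallis rejection rate is ~1.0. The null calibration draws
equal-mean visits on balanced 200/200/200 category groups for 1,000
replicates, giving a rejection rate near 0.05. These sizes keep the whole
suite and the acceptance script within a couple of minutes on one CPU while
leaving the Monte-Carlo error on the measured rates small (±0.015 at 1,000
replicates).

A known limitation: with the generator's own imbalanced category mix the
poor-health group is tiny (often a single record at n = 600), and the
Kruskal-Wallis chi-square approximation becomes conservative (measured null
rejection ≈ 0.025). The calibration is therefore measured on balanced
groups, where the approximation holds; with heavily imbalanced real data the
test errs on the conservative side.

## Numerical choices and degenerate inputs

- Rounding is half-up (ties away from zero), applied once — to the
  composite before categorization and to domain raws before banding.
- Config weights must sum to 1 within 1e-9; effective weights are exact by
  construction (division by the collective sum).
- Band tables are half-open intervals, so every continuous value maps to
  exactly one band; boundary equality goes to the worse band only where the
  guideline says so (e.g. BMI 30.0 is obese, LDL 4.1 is still moderate).
- Degenerate normalization ranges, all-missing domains, single-class ROC
  labels, zero-variance correlations and empty groups raise typed errors
  rather than returning NaNs.
- Every result embeds the sha256 digest of the exact configuration and the
  package version for auditability.

## Known limitations

- The scoreboard points and the instrument-to-risk policies are expert-style
  defaults, not fitted values; the config system exists precisely so they
  can be re-estimated (e.g. by item-response or SEM methods) without code
  changes.
- Unit conversion is out of scope: mg/dL biomarker inputs are rejected, not
  converted.
- The advice catalog ships complete in English with a partial Malay catalog
  as the localization hook; missing keys fall back to the default locale.
- Synthetic cohorts are independence-structured (see above) and should not
  be read as population-representative.
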