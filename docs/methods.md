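# Methods

## The prediction rule

The score is an additive points rule over twelve bedside predictors: the age
term (age in completed years; minus 10 for women) plus fixed weights for
nursing-home residency, five comorbidities (malignancy +30, liver cirrhosis
+20, heart failure / cerebrovascular disease / renal disease +10 each) and
five acute findings (altered mental status, respiratory rate ≥ 30/min,
systolic pressure < 90 mmHg at +20; pulse ≥ 125/min +10; temperature ≥ 40 °C
+15). Ages are taken as completed integer years (fractional ages are
floored). Vital signs are consumed as pre-dichotomized booleans; a
convenience constructor applies the cut-offs to raw measurements taken at ED
presentation. "Altered mental status" is accepted as a recorded boolean with
no imposed operationalization. No upper bound is placed on the total.

Risk classes: low < 75, intermediate 75–100 inclusive, high > 100. The
source tables disagree on whether a score of exactly 75 is low or
intermediate; we treat 75 and 100 as intermediate because those ranges carry
the published recommendations, and expose both boundaries through
`RiskThresholds` for sensitivity analyses.

## Endpoint definitions

*Complicated course* is the composite of 30-day death, ICU admission, or
more than 10 days of hospitalization (strictly; 10 days is not complicated).
We count hospitalization days attributable to the index episode over the
90-day follow-up window, because the endpoint list mixes the index stay with
total hospitalization days; restricting to the index stay is a caller-side
choice of the `hospital_days_90d` field.

*Clinical cure* requires being alive and afebrile (temperature < 38.0 °C,
mirroring the inclusion threshold — the test-of-cure threshold is not stated
explicitly) with symptoms absent (severity 0 on the 0–5 scale) or improved
by ≥ 2 points, and no additional antimicrobials for relapse.

*Bacteriologic cure* requires follow-up growth below 10⁴ cfu/mL in women or
10³ cfu/mL in men (strict bounds) together with disappearance of
leucocyturia. Missing follow-up cultures return *not evaluable* (`None`),
never failure: roughly a third of follow-up cultures in the trial were
sterile or contaminated, and cure denominators exclude them.

## Statistics

- **ROC AUC** uses the Mann-Whitney rank construction with mid-rank tie
  handling — the probability that a random positive outscores a random
  negative, ties counted half.
- **Predictive values** define *positive* as score ≥ cutoff; an empty
  predicted-positive or predicted-negative set makes the corresponding value
  not evaluable rather than zero.
- **Pearson chi-square** is computed without continuity correction on 1 df
  and equals the squared pooled two-proportion z statistic; **Fisher's
  exact** two-tailed p uses the probability-mass convention (sum of
  hypergeometric masses no larger than the observed table's). The default
  test-selection rule picks Fisher when any expected cell is below 5,
  overridable.
- **Risk differences** carry Wald normal-approximation intervals; reports
  round percentages half-up to whole points to match the published tables,
  while underlying values keep full precision.
- **Non-inferiority sample size** uses the standard normal-approximation
  formula n = (z_α + z_power)² · 2p(1−p) / margin² per arm under equal true
  rates. With the trial's stated inputs (5% control rate, 2.5% margin,
  one-tailed α = 0.025, 90% power) this gives ≈ 1598/arm, not the published
  326/arm, whose derivation is not reconstructable from the stated inputs;
  the formula is therefore validated by its properties and by exact binomial
  simulation at its own output, not against that figure.

## Synthetic cohort generator

The generator emulates the impact-trial cohort. Risk-class membership is
multinomial with prevalences 232/370, 93/370, 45/370 (low/intermediate/high).
Within a class, characteristics are drawn from class-specific proposals —
clipped-normal ages (means 52/80/88 years, reflecting the older, more
comorbid upper classes), sex (62/55/50% female) and independent Bernoulli
comorbidity/vital flags with probabilities rising across classes — and
accepted by rejection when the computed score lands in the class interval.
Rejection guarantees exact score/class consistency without inverting the
score; the proposals were chosen once to resemble the published cohort
demographics (median age ~60, 62% female overall) and are fully
configurable.

Latent outcomes per class: 30-day mortality 0/4/11%, 90-day mortality
0/6/13% (drawn as 30-day death plus a conditional increment), ICU admission
1/2/9% (independent of death, as no joint distribution is published), and
length of stay from a log-normal matched to the published medians 4/5/6 days
and IQR widths 3/4/4, discretized to whole days with a 1-day floor — only
medians and IQRs are printed, so the log-normal shape is a modeling choice.

What the generator does **not** emulate: correlations between individual
comorbidities, seasonal or center effects, the microbiology of the episodes,
and any dependence of secondary admission on patient covariates (it is a
per-policy Bernoulli). Tests passing on synthetic cohorts therefore
demonstrate internal consistency and calibration to the published marginal
rates, not performance on real patients.

## Trial simulator

Seven clusters (configurable) all start under the control policy; one
crosses to score-guided admission at the start of each period in a
randomized order until one cluster (configurable) remains uncrossed,
matching the realized allocation. Accrual is uniform per cluster-period
(default 8, ≈ 390 patients over 7 periods) with per-cluster overrides; no
between-cluster heterogeneity or calendar-time trend is modeled, since the
trial reported neither.

Admission policies: the control arm admits 92% of patients independent of
class (the published overall control rate), refinable per class. The
intervention arm follows the rule with physician overrule — low-risk
patients admitted with probability 0.33 (the published 33% overrule rate;
note the source's own tables imply 50 of 79 intervention low-risk patients
admitted, ≈ 63% — the stated 33% is kept as the default and the parameter is
configurable), intermediate-risk admitted with probability 29/35, high-risk
treated at home with probability 2/19. Home-treated patients draw a
secondary admission per arm: 1/17 under control (the low-risk control rate,
since the monitored metric counts only scores ≤ 100), 10/37 under the
intervention.

The monitor fires when cumulative intervention inclusions reach each entry
of the interim schedule (default: once, at 133) and computes the absolute
risk difference in secondary admissions (intervention − control, percentage
points) among home-treated patients with score ≤ 100; reaching the 20-point
threshold stops accrual. The full patient stream is generated before the
monitor scan, so a seed's trajectory is identical across thresholds —
lowering the threshold can only stop the same trajectory earlier.

Operating characteristics are plain Monte-Carlo summaries over independent
replicate trials (spawned seeds): early-stop probability, mean admission
reduction in percentage points, and power, defined as the fraction of trials
whose final two-sided Pearson chi-square on primary admission is significant
at 0.05 (Fisher's exact when a margin is degenerate), each with a binomial
or empirical standard error.

## Numerical and design choices

- All randomness flows through one `numpy` Generator per entry point;
  replicate trials use spawned `SeedSequence` children, so results are
  reproducible given a seed and independent across replicates.
- Percent rounding in reports is half-up (`floor(x + 0.5)`); for the values
  the reports print this matches the published tables (92, 72, 57, 27).
- Rejection sampling aborts with an error naming the class after 200 empty
  batches, which signals demographics that cannot reach the class interval.
- Problem sizes in the test suite (10⁵-patient calibration cohorts, 10⁴
  simulation replicates for power, 10³ replicate trials for the
  identical-policy stop rate) were chosen to keep Monte-Carlo error well
  inside the asserted three-standard-error bands while running in seconds.

## Known limitations

- The generator's within-class demographics are plausible but under-
  identified by the published marginals; only class prevalences, per-class
  outcome rates and stay medians/IQRs are calibrated quantities.
- Secondary admissions are modeled as a single per-arm probability; the
  published split between culture-driven recalls and symptom-driven returns
  (6 vs 4 of 10) is not modeled.
- The validation-cohort discrimination results (AUC 0.91/0.84, NPV/PPV at
  the 100-point cut-off) require patient-level data that are not available;
  the AUC and predictive-value implementations are instead verified against
  brute-force oracles and on synthetic cohorts.
- The published per-arm sample size and the abstract's p-value for the
  secondary-admission comparison are not reproducible from the stated
  inputs; the package reports its computed values.
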