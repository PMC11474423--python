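# Methods

This note records the statistical methods the package implements, the
choices made where the published instrument descriptions or analysis
conventions were ambiguous, and what the synthetic-data generator does and
does not emulate.

## Severity scores

All three scores are sums of banded vital-sign components.

**Modified GCS.** The motor component is restricted to three categories —
moves spontaneously or to verbal request (6 points), moves to pain only
(3), no movement (1) — reflecting simplified limb-movement data collection.
Eye (1–4) and verbal (1–5) components are conventional, so totals lie in
3–15 with some sums unreachable. For MEWS the total is converted to AVPU as
15 → Alert, 9–14 → Voice, 4–8 → Pain, 3 → Unresponsive; the conversion rule
is not fixed by any single authority, and this mapping is the standard
teaching correspondence (A ≈ 15, V ≈ 12, P ≈ 8, U ≈ 3), chosen because it is
deterministic from one number.

**Band-edge conventions.** Published band tables occasionally leave integer
gaps (heart rate exactly 40 between "<40" and "41–50"; systolic BP exactly
70; respiratory rate 8/9). These are closed by extending the more-severe
band to the boundary (HR ≤ 40 → 2, SBP ≤ 70 → 3, RR ≤ 8 → 2): conservative
triage never under-scores a sicker patient. MEWS temperature bands are real
intervals at 0.1 °C resolution ([35.0, 38.5) → 0, outside → 2); an SBP of
200 mmHg or more scores 2, matching the standard MEWS instrument.
Non-integer inputs are rounded half-up to the component's resolution before
banding. Every band table is data (`ScoreBandTable`, JSON round-trippable)
and validated at construction to tile the measurement's valid range exactly
once, so no input can fall between bands.

**Score ranges.** The instrument descriptions state MEWS 0–11 and UVA 0–12,
but the tabulated components sum to maxima of 14 (2+3+3+3+3) and 13
(2+1+1+1+2+4+2). The package scores the components literally and therefore
reports MEWS ∈ [0, 14] and UVA ∈ [0, 13]; the discrepancy is surfaced here
rather than silently reconciled. Similarly, the source's descriptive tables
disagree internally on the modified-GCS median (12 vs 15 for the same
population) and on HIV subgroup totals (685 vs 675); where a printed
percentage depends on the choice (HIV-positive mortality, 17%), the printed
subgroup denominator is used.

**Exploratory +HIV variants.** Adding HIV to MEWS/qSOFA uses a default
weight of 2 points — the UVA instrument's own HIV weight — exposed as a
parameter because no weight is fixed by the source analyses.

## ROC machinery

For an ordinal score, per-level alive/dead counts are the sufficient
statistic. The AUC is the tie-corrected Mann–Whitney probability
(concordant pairs plus half of tied pairs over all case–control pairs),
identical to the trapezoidal area under the empirical ROC step curve; the
package asserts this identity to 1e-12 as an internal consistency check.

Variances use DeLong's structural components: for case *i*,
V10ᵢ = (fraction of controls below, ties half); for control *j*, V01ⱼ
analogously. Var(AUC) = S₁₀/m + S₀₁/n with sample variances S and class
sizes m (cases), n (controls). Confidence intervals are Wald on the AUC
scale, clipped to [0, 1]; this choice reproduces the published qSOFA CI
(0.64–0.72) exactly from the printed contingency, which is why it is
adopted (the source does not state its CI method — this is inference, not
fact). The paired test for two scores on the same subjects uses the
component covariances, which collapse to the sample variances of the
per-subject component *differences*; p-values are two-sided normal, no
continuity correction. Components are computed via midranks in O(N log N),
and tested against explicit O(m·n) pair enumeration.

Operating characteristics use the positivity rule **score ≥ threshold**
(verified to reproduce the published threshold tables exactly):
sensitivity = % of deaths at or above t, specificity = % of survivors
below t. PPV/NPV at degenerate thresholds (empty predicted-positive or
-negative sets) are explicit nulls, mirroring the blank cells of published
tables. Percentages are carried at full precision internally and rounded
half-up to 2 dp only at the reporting layer.

**Ladder inversion.** A printed Se/Sp ladder at full 2-dp precision is
inverted to per-level counts by rounding n·Se/100 and n·Sp/100 to the
nearest integer and differencing cumulative totals; counts then sum exactly
to the class totals, and `threshold_ladder ∘ reconstruct` is the identity
on integer counts (property-tested).

## Regression models

Logistic fits are maximum likelihood by IRLS (statsmodels binomial GLM,
deviance tolerance 1e-13 so Wald SEs match closed forms to 1e-8), with SEs
from the inverse observed information. Perfect or quasi-complete separation
is flagged as non-convergence with a diagnostic, never silently corrected
(no Firth penalty); rank deficiency raises an error naming a collinear
column.

Score scales enter as categorical factors after sparse-level grouping:
the highest level with fewer than `min_count` (default 5) subjects is
repeatedly merged into its lower neighbour. The criterion cell is
configurable ("total" participants, or "dead" outcomes) because the source
describes it both ways in different places; neither reading is asserted as
the intended one. Reference level is 0 for qSOFA/UVA and 1 for MEWS. The
a-priori adjustment set is age group (six bands, 15–<25 … 65+, reference
15–<25), sex (reference female) and HIV status — except for UVA, where HIV
is a score component and requesting it raises an explicit refusal. Age
enters as the six-band grouping; Wald CIs throughout.

The Mann–Whitney test shares its tie-counting kernel with the AUC
(U/(n₁n₂) equals the tie-corrected AUC by construction) and uses the
tie-corrected normal approximation, cross-checked against an independent
implementation in tests.

## Synthetic cohort generator

The generator emulates the *statistical structure* of a four-site febrile
cohort, not its records. Per participant: site (weights 412/727/811/847 out
of 2797), inpatient status, sex and a six-band age draw follow the
published per-site margins; HIV is Bernoulli at site prevalence (0.2%, 14%,
51%, 20%). A single latent severity z ~ N(inpatient·1.5, 1) loads on all
vitals (per-unit-z shifts: temperature +0.1 °C, heart rate +6/min,
respiratory rate +1.5/min, SBP −6 mmHg, SpO₂ −3.5%) and on the probability
of reduced consciousness (logit −5.4 + 1.5 z). Vitals noise is skew-normal
matched to each site's published median and IQR (right-skewed for HR/RR,
left-skewed for SpO₂), truncated to physiological ranges; temperatures are
truncated below at 37.5 °C because enrolment required fever, so the
hypothermia bands of MEWS/UVA never fire on synthetic data — mirroring the
real cohort's stated limitation.

Death by follow-up is Bernoulli with logit = site intercept + 1.0·z +
ln(5)·HIV⁺ + 0.04·(age−32) + 1.2·inpatient. The HIV effect matches the
~5-fold adjusted odds of death observed for HIV; site intercepts
(−5.50, −6.19, −5.38, −5.63) were solved once by root-finding on a large
covariate draw so marginal site mortality hits the published 6%/2%/12%/6%,
giving ~6.6% overall (185/2797). Because SpO₂, deep GCS weighting and HIV
carry mortality signal that only UVA reads, generated cohorts reproduce the
qualitative finding UVA > {MEWS, qSOFA}, with AUCs around 0.69/0.67/0.78 at
the study's n. Time to death is log-normal with median 10 days (IQR ≈ 4–26)
for report realism only; no statistic uses it.

Missingness is missing-completely-at-random by default: the outcome is
blanked at 12% (loss to follow-up) and each of the seven score components
(five vitals, consciousness, HIV) independently at 3.6%, so ≈ 22.6% of
followed-up records are component-incomplete and ≈ 68% of enrolees survive
complete-case filtering — matching the real enrolment flow. The per-record
"20% incomplete" often quoted for the study is a fraction of *all*
enrolees, not of the followed-up; the 3.6% per-component rate is chosen to
reproduce the flow's endpoint (68% analysed).

**What passing tests do not show.** The generator is MCAR, single-factor
and conditionally independent across vitals given z; real cohorts have
outcome-dependent missingness, multimorbidity structure and site-specific
measurement practices. Reproducing the AUC *ordering* on synthetic data
validates the pipeline's statistics, not the clinical claim — the
deterministic re-analyses of the published summary tables do that part.

## Problem sizes and numerical choices

Simulation-backed checks use: 20 000 participants for calibration and
parameter-recovery checks (coefficients recovered within 3 SE), 2 000 null
replicates of n = 500 for the paired-test type-I error (99% binomial
envelope around 0.05), and 20 seeded cohorts of n = 2797 for the
score-ordering check (≥ 19/20 required). These sizes give stable
acceptance behaviour in well under a minute each. All randomness flows
from explicit integer seeds; identical configs give byte-identical cohorts
and reports (JSON with sorted keys). Degenerate inputs — empty outcome
classes, single-level scores, thresholds beyond the scale — return explicit
errors or flagged nulls, never silent defaults.

## Known limitations

- Wald intervals (AUC and OR) can misbehave near boundaries despite
  clipping; no bootstrap or profile-likelihood alternative is provided.
- No smoothed/parametric ROC, partial AUC, time-dependent ROC or
  calibration assessment; no survival modelling of time to death; no
  multiple imputation (only the two extreme outcome imputations).
- Ladder inversion assumes percentages printed at full 2-dp precision;
  heavier rounding can make the cumulative differencing infeasible, which
  is reported as an error rather than repaired.
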