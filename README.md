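# fevscore

Severity-score validation for febrile adults in low-resource settings.

Clinical severity scores promise cheap, fast triage: a handful of bedside
vitals summarised into a number that flags patients at risk of dying. This
package implements three such scores and the complete statistical machinery
used to validate them against 28-day mortality in multi-site febrile
cohorts (Lao PDR, Malawi, Mozambique, Zimbabwe), for epidemiologists and
biostatisticians who need the analysis to be exact, scriptable and testable
without access to the original patient-level data.

## What's inside

- **Score calculators** (`fevscore.scoring`) — MEWS (Modified Early Warning
  Score), qSOFA (quick Sequential Organ Failure Assessment) and UVA
  (Universal Vital Assessment), plus a modified Glasgow Coma Scale with a
  three-category motor component ({6, 3, 1}) and its AVPU conversion. Band
  tables are data (JSON-serialisable), not code.
- **ROC engine** (`fevscore.roc`) — for an ordinal score with per-level
  alive/dead counts $(a_\ell, d_\ell)$, the tie-corrected Mann–Whitney AUC

  $$\widehat{\mathrm{AUC}} = \frac{\sum_{\ell' < \ell} a_{\ell'} d_\ell +
  \tfrac12 \sum_\ell a_\ell d_\ell}{N_\text{alive}\, N_\text{dead}},$$

  DeLong structural-component variance ($S_{10}/m + S_{01}/n$) with Wald
  CIs, the paired DeLong test for correlated AUCs, operating characteristics
  (Se/Sp/PPV/NPV at the *score ≥ threshold* rule), and exact inversion of
  published sensitivity/specificity ladders back to per-level counts.
- **Models** (`fevscore.models`) — logistic regression by IRLS with Wald
  CIs, sparse score-level grouping (merge levels with < 5 subjects from the
  top of the scale), chi-squared and tie-corrected Mann–Whitney tests. UVA
  models refuse HIV as a covariate, since HIV is a UVA component.
- **Cohort simulator** (`fevscore.cohort_sim`) — a four-site synthetic
  febrile-cohort generator (latent-severity factor model, site-specific HIV
  prevalence and mortality, ~12% loss to follow-up, component-wise
  missingness) so every pipeline stage is testable end to end.
- **Pipeline + CLI** (`fevscore.pipeline`, `fevscore`) — complete-case
  filtering, all AUCs and pairwise tests, subgroup and missing-outcome
  sensitivity analyses, JSON/Markdown reports.

## Worked example

Re-derive the published headline numbers from the printed summary tables
(`python examples/published_tables_reanalysis.py`):

```
qSOFA AUC 0.68 (95% CI 0.64-0.72) from 185 deaths / 2612 survivors
MEWS  AUC 0.67 (ladder inverted to per-level counts)
UVA   AUC 0.82 (ladder inverted to per-level counts)
qSOFA >= 2: Se 30.81%, Sp 93.19%, PPV 24.26%, NPV 95.00%
```

The qSOFA AUC of 0.68 means a randomly chosen participant who died
outranked a randomly chosen survivor 68% of the time (ties split evenly) —
modest discrimination; UVA's 0.82 is markedly better. At the usual qSOFA ≥ 2
cut-off, sensitivity is only ~31%: most eventual deaths are missed.

Simulate a study-sized cohort and validate end to end
(`python examples/simulate_and_validate.py`):

```
enrolled 4102, lost 480, incomplete 843, analysed 2779
MEWS  AUC 0.71 (0.67-0.75)
QSOFA AUC 0.71 (0.67-0.75)
UVA   AUC 0.82 (0.78-0.85)
mews_vs_qsofa: delta AUC -0.003, p = 0.8592
mews_vs_uva: delta AUC -0.111, p = 0.0000
qsofa_vs_uva: delta AUC -0.108, p = 0.0000
```

On synthetic cohorts UVA outperforms both other scores (paired DeLong
p < 0.001) because the generator routes mortality signal through channels
only UVA reads: oxygen saturation, a heavy weight on reduced consciousness,
and HIV status.

The other examples (`examples/score_a_patient.py`,
`examples/missing_outcome_sensitivity.py`) score a single patient and probe
robustness to loss to follow-up. The same functionality is available from
the shell:

```sh
fevscore simulate --seed 11 --out cohort.csv
fevscore score --in cohort.csv --out scored.csv
fevscore analyze --in cohort.csv --report out/
fevscore fixtures --out fixtures/
```

## Notes

- The published instrument descriptions state ranges MEWS 0–11 and UVA
  0–12, but their tabulated components sum to maxima of 14 and 13; this
  package scores the components literally (see `docs/methods.md`).
- Missing statistics (e.g. PPV with no predicted positives, subgroup AUCs
  with a single outcome class) are reported as explicit nulls with reasons,
  never as zeros.
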