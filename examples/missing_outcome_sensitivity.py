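"""How robust are the AUCs to participants lost to follow-up?

Two extreme imputations bracket the truth: assume every lost participant
survived, then assume every one died.  The AUCs barely move under the
first and attenuate under the second, but the ranking of the scores holds.
"""

from fevscore import SimConfig, apply_missingness, run_validation, simulate_cohort

config = SimConfig(seed=23, n_participants=4102)
cohort = apply_missingness(simulate_cohort(config), config)
report = run_validation(cohort)

rows = [("complete case", report.aucs)]
for mode in ("alive", "dead"):
    block = report.sensitivity[f"missing_outcome_set_to_{mode}"]
    rows.append((f"missing -> {mode}", block["aucs"]))

print(f"{'analysis':<18s} {'MEWS':>6s} {'qSOFA':>6s} {'UVA':>6s}")
for label, aucs in rows:
    print(f"{label:<18s} "
          f"{aucs['mews']['auc']:6.2f} {aucs['qsofa']['auc']:6.2f} "
          f"{aucs['uva']['auc']:6.2f}")
print("Setting all lost participants to 'dead' dilutes every score "
      "(the imputed deaths are unrelated to enrolment vitals), yet UVA "
      "stays ahead.")
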