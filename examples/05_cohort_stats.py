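"""The predictive-statistics layer on a synthetic two-group cohort.

Generates an 84-patient cohort matching the published group summaries,
screens features, fits univariable and backward-stepwise logistic models,
and runs ROC analyses — plus the exactly-recomputable published-count
EMVI analysis.
"""

from tddmri.pipeline import RunConfig, run_cohort_stats

report = run_cohort_stats(config=RunConfig(seed=3, out_dir="results/example_stats"))

print("univariable odds ratios (synthetic cohort, outcome = LVI):")
for feat, rec in report["univariable"].items():
    print(f"  {feat:<18} OR {rec['odds_ratio']:>7.3f} "
          f"(95% CI {rec['ci'][0]:.3f}-{rec['ci'][1]:.3f})  p={rec['p']:.4f}")
print(f"stepwise candidates: {report['stepwise']['candidates']}")
print(f"retained after backward elimination: {report['stepwise']['retained']}")
print("\nROC (synthetic cohort):")
for feat, rec in report["roc"].items():
    print(f"  {feat:<18} AUC {rec['auc']:.3f}  cutoff {rec['cutoff']:.3f}  "
          f"sens {rec['sensitivity']:.3f}  spec {rec['specificity']:.3f}")

fx = report["emvi_fixture"]
print("\npublished-count EMVI 2x2 (exact recomputation):")
print(f"  OR {fx['odds_ratio']:.3f} (95% CI {fx['ci'][0]:.3f}-{fx['ci'][1]:.3f}); "
      f"AUC {fx['auc']:.3f}, sens {fx['sensitivity']:.3f}, spec {fx['specificity']:.3f}")
print("\nThe synthetic cohort reproduces the published summary statistics, so "
      "the strong group separations (icvf, cellularity) drive selection and "
      "high AUCs, while the EMVI block is an exact function of the printed "
      "counts.  Odds ratios are per unit of the feature — icvf spans only "
      "~0.1-0.5, so its per-unit OR is extreme by construction — and an AUC "
      "below 0.5 (adc_pgse) marks a feature that predicts in the opposite "
      "direction (lower ADC in the LVI-positive group).")
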