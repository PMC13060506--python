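"""Simulate a complete 64-participant trial and run every analysis stage,
printing the group-by-phase consumption pattern and concordance statistics."""

import json

from eftrial import CohortConfig, run_pipeline

report = run_pipeline(config=CohortConfig(n_per_group=32, seed=42),
                      out_dir="trial_output")

print("drinks/drinking day by group and phase:")
for key in sorted(report["consumption"]):
    v = report["consumption"][key]
    print(f"  {key:<18} {v['drinks_per_drinking_day']:.2f}")

c = report["concordance"]
print(f"\nbreath/report concordance: OR {c['odds_ratio']:.1f}, "
      f"AUC {c['auc']:.2f} over {c['n_days_2x2']} days")
print("best missingness model:",
      report["adherence_selection"]["best_terms"])
print("\nall interface files and report.json written to trial_output/")
# Under the default configuration the EFT group's drinking declines across
# monitoring phases while CET shows only a transient dip, and rising
# missingness makes 'phase' the selected predictor of missing submissions.
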