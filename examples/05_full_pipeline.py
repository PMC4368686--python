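"""Run the complete risk-stratification analysis on a synthetic cohort.

Simulates the default 139-subject cohort, extracts features from a
stationary 5-minute segment per subject, splits 60/40, selects features
and tunes six classifier families on the training part only, and
evaluates everything on the held-out subjects. Takes about a minute.
"""

from hrvrisk import PipelineConfig, run_full_pipeline
from hrvrisk.synthetic import CohortConfig

report = run_full_pipeline(PipelineConfig(cohort=CohortConfig(seed=1)))

print(f"{report['n_subjects']} subjects "
      f"({report['n_high_risk']} high-risk); "
      f"train {report['split']['n_train']} / test {report['split']['n_test']}")
print(f"\n{'family':6s} {'AUC%':>6s} {'ACC%':>6s} {'SEN%':>6s} {'SPE%':>6s}  features")
for fam, m in report["models"].items():
    print(f"{fam:6s} {m['AUC_pct']:6.1f} {m['ACC_pct']:6.1f} "
          f"{m['SEN_pct']:6.1f} {m['SPE_pct']:6.1f}  {m['model']['feature_set']}")
print(f"\nbest family by test AUC: {report['best_family']}")
rt = report["rule_tree"]["cohort"]
print(f"rule tree on the whole cohort: SEN {rt['SEN_pct']:.1f}%, "
      f"SPE {rt['SPE_pct']:.1f}%")
lv = report["echographic"]["lvmi"]
print(f"LVMi single-parameter comparator: AUC {lv['AUC_pct']:.1f}%")
# Sensitivity = flagged fraction of event subjects; specificity = the
# event-free fraction classified low-risk. The HRV-based classifiers
# should clearly beat the echographic single-parameter baseline.
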