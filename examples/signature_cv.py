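"""Multi-omics prognostic signature with cross-validated evaluation.

DE screening, per-layer importance ranking truncated to fixed sizes, one
penalized logistic refit — evaluated by stratified fivefold CV with
balanced bootstrap training folds.
"""

import omicsig as og

cohort, truth = og.simulate_cohort(og.SimConfig(seed=7))
cohort = og.purity_filter(cohort, 0.60)
print(f"{len(cohort.sample_ids)} samples retained after the purity cut")

de = og.screen_de_features(cohort, alpha=0.05)
print("DE features per layer:", {k: len(v) for k, v in de.items()})

cfg = og.SignatureConfig(n_bootstrap=40, seed=7)
model = og.build_signature(cohort, de, cfg)
print("signature sizes:",
      {k: len(v) for k, v in model.layer_features.items()})

report = og.cross_validate(cohort, cfg, k=5, seed=7)
print(f"CV accuracy {report.accuracy:.3f}, error {report.error_rate:.3f}, "
      f"MCC {report.mcc:.3f} (best fold {report.best_fold_accuracy:.3f})")

# The signature keeps 5/11/30/4/3 features per layer; on the strong-signal
# synthetic cohort the survival groups separate almost perfectly, so
# accuracy near 1 and MCC near 1 are expected.
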