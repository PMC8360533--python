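"""Generate a synthetic radiomics-style feature table with a known oracle AUC.

Builds the "simple task" stand-in (109 vs. 58 subjects, 400 features,
calibrated so the Bayes-optimal discriminant scores AUC 0.95) and writes
it as CSV.
"""

from dataclasses import replace

from splitgap import GeneratorConfig, calibrate_shift, generate_dataset, theoretical_auc

skeleton = GeneratorConfig(n_class0=109, n_class1=58, p_total=400, seed=0)
delta = calibrate_shift(0.95, skeleton)
config = replace(skeleton, delta=delta)

table = generate_dataset(config)
table.to_csv("simple_task.csv")

print(f"per-feature shift delta = {delta:.4f} (standardized units)")
print(f"oracle (Bayes) AUC      = {theoretical_auc(config):.4f}")
print(f"table: {table.n_samples} subjects x {table.n_features} features, "
      f"class counts {table.class_counts()}")
# The oracle AUC is the ceiling any classifier can reach on this task; the
# experiments measure how far small-sample fits land below it, and how much
# that depends on the train-test split.
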