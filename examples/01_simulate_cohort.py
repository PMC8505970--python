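"""Simulate a synthetic training cohort shaped like the pooled study cohorts.

46 baseline mucosal expression profiles (20 responders, 26 non-responders)
across two source-dataset batches, 1000 genes with a planted 30-gene
signature (28 genes lower in responders, 2 higher).
"""

import numpy as np

from ifxmps import default_training_cohort_config, simulate_cohort

config = default_training_cohort_config(seed=1)
expr, pheno, truth = simulate_cohort(config)

print(f"expression matrix: {expr.n_genes} genes x {expr.n_samples} samples (log2 scale)")
print(f"responders: {pheno.response.count('responder')}, "
      f"non-responders: {pheno.response.count('non_responder')}")
print(f"batches: { {b: pheno.batch.count(b) for b in sorted(set(pheno.batch))} }")
print(f"planted signature: {len(truth)} genes "
      f"({truth.directions.count('down')} down / {truth.directions.count('up')} up in responders)")

is_resp = np.array([r == "responder" for r in pheno.response])
lfc = expr.values[:, is_resp].mean(axis=1) - expr.values[:, ~is_resp].mean(axis=1)
print(f"empirical log2FC of first planted gene ({truth.gene_ids[0]}): {lfc[0]:+.2f} "
      f"(planted {-config.delta:+.1f}, batch offsets and noise still present)")
# The planted log2FC is responder-minus-non-responder, so "down" genes sit near
# -delta; downstream stages must remove the batch offset before testing.
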