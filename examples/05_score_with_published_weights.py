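"""Score samples with the packaged published 30-gene Gene Weight table.

The table ships with the package: one weight per signature gene, direction
"up" (higher in responders) for C10orf99 and ADH1C and "down" for the other
28. A sample's mPS is the sum of the weights of the genes whose binary Gene
Score is 1, so single-gene indicator rows read individual weights back out.
"""

import numpy as np

from ifxmps import compute_mps, load_published_weights
from ifxmps.scoring import GeneScoreTable

weights = load_published_weights()
print(f"{len(weights)} published Gene Weights, "
      f"sum = {weights.weights.sum():.4f}, "
      f"range {weights.weights.min():.4f} .. {weights.weights.max():.4f}")

genes = list(weights.gene_ids)
for gene in ("IL6", "MME", "PTGS2"):
    scores = np.zeros((1, 30), dtype=int)
    scores[0, genes.index(gene)] = 1
    table = GeneScoreTable(
        sample_ids=["indicator"], gene_ids=genes, scores=scores,
        response=np.array([1]), medians=np.zeros(30),
        directions=list(weights.directions),
    )
    mps = compute_mps(table, weights)[0]
    print(f"sample scoring 1 only for {gene:6s} -> mPS = {mps}")

all_on = GeneScoreTable(
    sample_ids=["all_on"], gene_ids=genes,
    scores=np.ones((1, 30), dtype=int), response=np.array([1]),
    medians=np.zeros(30), directions=list(weights.directions),
)
print(f"sample scoring 1 for every gene -> mPS = {compute_mps(all_on, weights)[0]:.4f} "
      "(the attainable maximum under non-negative weights)")
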