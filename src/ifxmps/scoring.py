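"""Median-threshold binarisation of signature genes: the "Gene Score" table.

Each signature gene's expression is recoded per sample against the gene's
median over ALL samples of the cohort (both classes pooled). For a gene
expressed higher in responders ("up"): score 1 iff the value is strictly
above the median, else 0. For a "down" gene the rule is the exact complement:
score 1 iff the value is at or below the median. Under this orientation a
score of 1 co-varies with response = 1 for every signature gene, so a
weighted sum of scores is largest for responders.

The rule is rank-based: scores are invariant under any strictly monotone
transform of a gene's values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import NON_RESPONDER, RESPONDER, ExpressionMatrix, Phenotype

__all__ = ["GeneScoreTable", "binarize_gene", "label_response", "build_gene_score_table"]


@dataclass
class GeneScoreTable:
    """Binary samples x signature-genes score matrix plus the response column.

    ``medians`` records the per-gene thresholds used, so the table can be
    reproduced from them; validation cohorts are always scored with their OWN
    medians, never the training cohort's.
    """

    sample_ids: list[str]
    gene_ids: list[str]
    scores: np.ndarray  # samples x genes, 0/1
    response: np.ndarray  # 0/1 per sample (1 = responder)
    medians: np.ndarray
    directions: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=int)
        self.response = np.asarray(self.response, dtype=int)
        self.medians = np.asarray(self.medians, dtype=float)
        n, g = len(self.sample_ids), len(self.gene_ids)
        if self.scores.shape != (n, g):
            raise ValueError(f"score matrix shape {self.scores.shape} != ({n}, {g})")
        if not np.isin(self.scores, (0, 1)).all():
            raise ValueError("scores must be binary")
        if not np.isin(self.response, (0, 1)).all():
            raise ValueError("response must be binary")
        if len(self.medians) != g or len(self.directions) != g:
            raise ValueError("medians/directions must align with gene_ids")

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.scores, index=self.sample_ids, columns=self.gene_ids)
        frame["response"] = self.response
        return frame


def binarize_gene(values, direction: str) -> np.ndarray:
    """Binary score vector for one gene's per-sample expression values.

    The median is the standard midpoint median over all supplied samples.
    "up": 1 iff value > median (strict; a value equal to the median scores 0).
    "down": the complement, 1 iff value <= median.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("values must be a non-empty 1-d vector")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    above = values > np.median(values)
    return above.astype(int) if direction == "up" else (~above).astype(int)


def label_response(pheno: Phenotype) -> np.ndarray:
    """Responders -> 1, non-responders -> 0 (Phenotype validates the labels)."""
    mapping = {RESPONDER: 1, NON_RESPONDER: 0}
    return np.array([mapping[r] for r in pheno.response], dtype=int)


def build_gene_score_table(
    expr: ExpressionMatrix,
    signature: dict[str, str],
    pheno: Phenotype,
) -> GeneScoreTable:
    """Score a cohort against a signature (gene -> direction mapping).

    Medians are computed from THIS cohort's samples, column-wise per gene.
    All signature genes must be present in the expression matrix.
    """
    genes = list(signature)
    missing = sorted(set(genes) - set(expr.gene_ids))
    if missing:
        raise KeyError(f"signature genes absent from expression matrix: {missing}")
    pheno = pheno.aligned_to(expr.sample_ids)
    sub = expr.subset_genes(genes)
    scores = np.column_stack(
        [binarize_gene(sub.values[i], signature[g]) for i, g in enumerate(genes)]
    )
    medians = np.median(sub.values, axis=1)
    return GeneScoreTable(
        sample_ids=list(expr.sample_ids),
        gene_ids=genes,
        scores=scores,
        response=label_response(pheno),
        medians=medians,
        directions=[signature[g] for g in genes],
    )
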