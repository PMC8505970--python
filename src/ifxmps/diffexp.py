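"""Probe collapsing, batch-effect removal, and differential expression.

Differentially expressed genes (DEGs) between baseline responders and
non-responders are screened with a Welch two-sample t-test per gene,
Benjamini-Hochberg FDR adjustment, and the strict thresholds fdr < 0.05 and
|log2FC| > 1. The fold-change orientation is responder minus non-responder
throughout, so the bulk of the published signature (higher in non-responders)
has negative log2FC, direction "down".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import RESPONDER, ExpressionMatrix, Phenotype

__all__ = [
    "DEGRecord",
    "collapse_duplicates",
    "remove_batch_effect",
    "differential_expression",
    "benjamini_hochberg",
    "filter_degs",
]

logger = logging.getLogger(__name__)

FDR_THRESHOLD = 0.05
LFC_THRESHOLD = 1.0


@dataclass
class DEGRecord:
    gene_id: str
    log2fc: float  # responder mean - non-responder mean
    p_value: float
    fdr: float

    @property
    def direction(self) -> str:
        """"up" = higher in responders (log2fc > 0)."""
        return "up" if self.log2fc > 0 else "down"


def collapse_duplicates(expr) -> ExpressionMatrix:
    """Collapse repeated gene symbols, keeping the probe with the highest mean.

    Accepts a probe-level ``pandas.DataFrame`` (index = gene symbol, possibly
    duplicated, columns = samples) or an already-unique ``ExpressionMatrix``
    (returned collapsed-by-identity). Row order follows first appearance of
    each symbol.
    """
    frame = expr.to_frame() if isinstance(expr, ExpressionMatrix) else expr
    if not frame.index.has_duplicates:
        return ExpressionMatrix.from_frame(frame)
    means = frame.mean(axis=1).to_numpy()
    keep: dict[str, int] = {}
    for i, symbol in enumerate(frame.index):
        j = keep.get(symbol)
        if j is None or means[i] > means[j]:
            keep[symbol] = i
    rows = list(keep.values())
    collapsed = pd.DataFrame(
        frame.to_numpy()[rows, :], index=list(keep.keys()), columns=frame.columns
    )
    return ExpressionMatrix.from_frame(collapsed)


def remove_batch_effect(expr: ExpressionMatrix, pheno: Phenotype) -> ExpressionMatrix:
    """Remove additive batch offsets by gene-wise linear modelling.

    Per gene, a least-squares model with intercept, response indicator and
    batch indicators is fit, and the fitted batch terms are subtracted after
    centring them so each gene's grand mean is preserved. Response-associated
    signal is protected by including the response term in the model. A single
    batch is a no-op; a batch containing only one class is recorded as a
    confounding warning in the result metadata.
    """
    pheno = pheno.aligned_to(expr.sample_ids)
    batches = sorted(set(pheno.batch))
    if len(batches) < 2:
        logger.info("single batch %r: batch removal is a no-op", batches)
        return expr

    metadata = dict(expr.metadata)
    for b in batches:
        classes = {r for r, pb in zip(pheno.response, pheno.batch) if pb == b}
        if len(classes) < 2:
            msg = f"batch {b!r} contains a single class; batch and response are confounded"
            logger.warning(msg)
            metadata.setdefault("warnings", []).append(msg)

    n = expr.n_samples
    is_resp = np.array([r == RESPONDER for r in pheno.response], dtype=float)
    dummies = np.column_stack(
        [[1.0 if pb == b else 0.0 for pb in pheno.batch] for b in batches[1:]]
    )
    design = np.column_stack([np.ones(n), is_resp, dummies])
    # shared design across genes: one pseudoinverse, applied to all genes at once
    beta = np.linalg.pinv(design) @ expr.values.T  # (p, n_genes)
    batch_term = dummies @ beta[2:, :]  # (n, n_genes)
    batch_term -= batch_term.mean(axis=0, keepdims=True)  # preserve grand mean
    corrected = expr.values - batch_term.T
    return ExpressionMatrix(list(expr.gene_ids), list(expr.sample_ids), corrected, metadata)


def _welch(resp: np.ndarray, nonresp: np.ndarray) -> np.ndarray:
    """Vectorised two-sided Welch t-test p-values, rows = genes.

    Zero variance in both classes: p = 1 if the means are equal else 0
    (the limiting behaviour as the variances shrink; avoids NaN propagation).
    """
    n1, n2 = resp.shape[1], nonresp.shape[1]
    m1, m2 = resp.mean(axis=1), nonresp.mean(axis=1)
    v1, v2 = resp.var(axis=1, ddof=1), nonresp.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    p = np.ones(resp.shape[0])
    degenerate = se2 == 0
    p[degenerate & (m1 != m2)] = 0.0
    ok = ~degenerate
    if np.any(ok):
        t = (m1[ok] - m2[ok]) / np.sqrt(se2[ok])
        df = se2[ok] ** 2 / (
            (v1[ok] / n1) ** 2 / (n1 - 1) + (v2[ok] / n2) ** 2 / (n2 - 1)
        )
        p[ok] = 2.0 * stats.t.sf(np.abs(t), df)
    return p


def differential_expression(expr: ExpressionMatrix, pheno: Phenotype) -> list[DEGRecord]:
    """Per-gene responder-vs-non-responder test.

    log2FC = responder mean - non-responder mean; two-sided Welch t-test;
    Benjamini-Hochberg FDR. Both classes need >= 2 samples.
    """
    pheno = pheno.aligned_to(expr.sample_ids)
    is_resp = np.array([r == RESPONDER for r in pheno.response])
    if is_resp.sum() < 2 or (~is_resp).sum() < 2:
        raise ValueError(
            "need >= 2 samples per class for a variance estimate "
            f"(got {int(is_resp.sum())} responders, {int((~is_resp).sum())} non-responders)"
        )
    resp, nonresp = expr.values[:, is_resp], expr.values[:, ~is_resp]
    lfc = resp.mean(axis=1) - nonresp.mean(axis=1)
    p = _welch(resp, nonresp)
    fdr = benjamini_hochberg(p)
    return [
        DEGRecord(g, float(l), float(pv), float(q))
        for g, l, pv, q in zip(expr.gene_ids, lfc, p, fdr)
    ]


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR), clipped to 1.

    fdr_(i) = min_{j >= i} m * p_(j) / j over the ascending order statistics,
    mapped back to the input order. Order-preserving in the p-value ranks.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-d array")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    fdr_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    fdr = np.empty(m)
    fdr[order] = np.minimum(fdr_sorted, 1.0)
    return fdr


def filter_degs(
    records: list[DEGRecord],
    fdr_threshold: float = FDR_THRESHOLD,
    lfc_threshold: float = LFC_THRESHOLD,
) -> list[DEGRecord]:
    """Keep records with fdr < threshold AND |log2FC| > threshold (both strict)."""
    return [
        r for r in records if r.fdr < fdr_threshold and abs(r.log2fc) > lfc_threshold
    ]
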