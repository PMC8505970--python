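"""Molecular prognostic score (mPS), ROC/AUC evaluation, and orchestration.

mPS(sample) = sum over signature genes of GeneScore(sample, gene) x
GeneWeight(gene). The end-to-end training pipeline chains: probe collapsing ->
batch-effect removal -> differential expression -> DEG filtering ->
random-forest ranking -> top-30 selection -> Gene Score binarisation -> ANN
training -> Gene Weight extraction -> mPS -> ROC/AUC. External validation
re-binarises the validation cohort against its OWN medians (the "updated"
Gene Score) and reuses the training weights and directions unchanged.

AUC is the tie-corrected Mann-Whitney rank statistic — the probability that a
random responder's mPS exceeds a random non-responder's, ties counted one
half — and is asserted to agree with the trapezoidal area under the empirical
ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from . import __version__
from .ann import ANNHyperparams, extract_gene_weights, train_ann
from .diffexp import (
    FDR_THRESHOLD,
    LFC_THRESHOLD,
    collapse_duplicates,
    differential_expression,
    filter_degs,
    remove_batch_effect,
)
from .io import ExpressionMatrix, GeneWeightTable, Phenotype
from .rf import DEFAULT_N_TREES, rank_genes_rf, top_k
from .scoring import GeneScoreTable, build_gene_score_table

__all__ = [
    "MPSResult",
    "TrainedModel",
    "PipelineConfig",
    "compute_mps",
    "auc",
    "roc_curve",
    "evaluate_mps",
    "run_training_pipeline",
    "validate_external",
]


@dataclass
class MPSResult:
    """Per-sample mPS with its ROC evaluation."""

    sample_ids: list[str]
    mps: np.ndarray
    response: np.ndarray  # 0/1, 1 = responder
    roc_points: np.ndarray  # (k, 2) columns: FPR, TPR
    auc: float


@dataclass
class TrainedModel:
    """Reusable artefact of the training pipeline: signature + weights + provenance."""

    signature: dict[str, str]  # gene -> direction (relative to responders)
    weights: GeneWeightTable
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.signature) != set(self.weights.gene_ids):
            raise ValueError("signature and weight table cover different gene sets")


@dataclass
class PipelineConfig:
    """Thresholds, sizes and seeds of the training pipeline; all logged in provenance."""

    fdr_threshold: float = FDR_THRESHOLD
    lfc_threshold: float = LFC_THRESHOLD
    n_trees: int = DEFAULT_N_TREES
    k: int = 30
    ann: ANNHyperparams = field(default_factory=ANNHyperparams)
    seed: int = 0


def compute_mps(table: GeneScoreTable, weights: GeneWeightTable) -> np.ndarray:
    """Weighted sum of binary scores per sample; every scored gene needs a weight."""
    missing = sorted(set(table.gene_ids) - set(weights.gene_ids))
    if missing:
        raise KeyError(f"scored genes without a weight: {missing}")
    w = np.array([weights.weight_of(g) for g in table.gene_ids])
    return table.scores @ w


def auc(scores, labels) -> float:
    """Tie-corrected Mann-Whitney AUC.

    (sum of the positives' mid-ranks - n+(n+ + 1)/2) / (n+ n-); equals the
    probability that a random positive outscores a random negative, with
    tied pairs counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both positive and negative labels")
    ranks = rankdata(scores)  # mid-ranks for ties
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_curve(scores, labels) -> np.ndarray:
    """Empirical ROC points (FPR, TPR), anchored at (0,0) and (1,1).

    Thresholds sweep the unique score values from high to low; every
    threshold is kept (no convex-hull thinning).
    """
    labels = np.asarray(labels, dtype=int)
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("ROC needs both positive and negative labels")
    fpr, tpr, _ = _sk_roc_curve(labels, np.asarray(scores, dtype=float),
                                drop_intermediate=False)
    return np.column_stack([fpr, tpr])


def evaluate_mps(
    sample_ids: list[str], mps: np.ndarray, response: np.ndarray
) -> MPSResult:
    """Bundle mPS values with ROC points and AUC; internal consistency enforced.

    The rank-statistic AUC and the trapezoidal area under the ROC points must
    agree to 1e-12 — two independent routes to the same quantity.
    """
    points = roc_curve(mps, response)
    area = auc(mps, response)
    trapezoid = float(np.trapezoid(points[:, 1], points[:, 0]))
    if abs(area - trapezoid) > 1e-12:
        raise AssertionError(
            f"rank AUC {area!r} and trapezoidal ROC area {trapezoid!r} disagree"
        )
    return MPSResult(list(sample_ids), np.asarray(mps, float),
                     np.asarray(response, int), points, area)


def run_training_pipeline(
    expr: ExpressionMatrix,
    pheno: Phenotype,
    config: PipelineConfig | None = None,
) -> tuple[TrainedModel, MPSResult]:
    """Train the full predictive model on one cohort.

    Raises if fewer than ``config.k`` genes survive the DEG filter (relax the
    thresholds or lower k in that case). Re-running with identical inputs and
    config reproduces the TrainedModel bit-exactly.
    """
    cfg = config or PipelineConfig()
    expr = collapse_duplicates(expr)
    expr = remove_batch_effect(expr, pheno)
    records = differential_expression(expr, pheno)
    degs = filter_degs(records, cfg.fdr_threshold, cfg.lfc_threshold)
    if len(degs) < cfg.k:
        raise ValueError(
            f"only {len(degs)} genes pass fdr<{cfg.fdr_threshold} and "
            f"|log2FC|>{cfg.lfc_threshold}; need >= {cfg.k} "
            "(relax the thresholds or lower k)"
        )
    deg_expr = expr.subset_genes([r.gene_id for r in degs])
    ranked = rank_genes_rf(deg_expr, pheno, n_trees=cfg.n_trees, seed=cfg.seed)
    selected = top_k(ranked, cfg.k)
    directions = {r.gene_id: r.direction for r in degs}
    signature = {g: directions[g] for g in selected}

    table = build_gene_score_table(expr, signature, pheno)
    model_ann = train_ann(table, cfg.ann, seed=cfg.seed)
    weights = extract_gene_weights(model_ann, table.gene_ids, table.directions)

    mps = compute_mps(table, weights)
    result = evaluate_mps(table.sample_ids, mps, table.response)
    trained = TrainedModel(
        signature=signature,
        weights=weights,
        provenance={
            "seed": cfg.seed,
            "n_trees": cfg.n_trees,
            "k": cfg.k,
            "fdr_threshold": cfg.fdr_threshold,
            "lfc_threshold": cfg.lfc_threshold,
            "ann": {
                "learning_rate": cfg.ann.learning_rate,
                "epochs": cfg.ann.epochs,
                "n_hidden": cfg.ann.n_hidden,
                "init": cfg.ann.init,
            },
            "n_degs": len(degs),
            "training_samples": len(pheno),
            "version": __version__,
        },
    )
    return trained, result


def validate_external(
    model: TrainedModel,
    expr_val: ExpressionMatrix,
    pheno_val: Phenotype,
) -> MPSResult:
    """Score an external cohort with a trained model.

    The validation cohort is preprocessed the same way as training (probe
    collapsing, batch removal against its own batches), Gene Scores are
    recomputed from the validation cohort's own medians, and the training
    Gene Weights and directions are reused unchanged.
    """
    expr_val = collapse_duplicates(expr_val)
    expr_val = remove_batch_effect(expr_val, pheno_val)
    table = build_gene_score_table(expr_val, model.signature, pheno_val)
    mps = compute_mps(table, model.weights)
    return evaluate_mps(table.sample_ids, mps, table.response)
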