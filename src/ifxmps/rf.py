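"""Random-forest ranking of DEGs by out-of-bag permutation importance.

The importance reported is the mean decrease of accuracy: for each tree, the
out-of-bag (OOB) accuracy is compared with the OOB accuracy after permuting
one feature's values among the OOB samples, and the drop is averaged over
trees. This is the importance reported by the classical R randomForest
implementation (unscaled variant); a scaled variant (divided by the standard
error over trees) is available via a flag.

The forest itself is a bagging ensemble of CART trees
(``sklearn.tree.DecisionTreeClassifier``) built here explicitly so the
bootstrap membership of every tree — and hence its OOB set — is known.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .io import RESPONDER, ExpressionMatrix, Phenotype

__all__ = ["RankedGeneList", "rank_genes_rf", "top_k"]

DEFAULT_N_TREES = 500


@dataclass
class RankedGeneList:
    """Genes sorted by importance (mean decrease of accuracy), descending.

    Ties are broken lexicographically by gene id so the top-k selection is
    reproducible; ranks are 1..n.
    """

    gene_ids: list[str]
    importances: np.ndarray
    ranks: list[int]
    n_trees: int
    seed: int

    def __post_init__(self) -> None:
        self.importances = np.asarray(self.importances, dtype=float)
        if self.ranks != list(range(1, len(self.gene_ids) + 1)):
            raise ValueError("ranks must be 1..n with no gaps")

    def __len__(self) -> int:
        return len(self.gene_ids)


def rank_genes_rf(
    expr: ExpressionMatrix,
    pheno: Phenotype,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    scaled: bool = False,
) -> RankedGeneList:
    """Fit a random forest (samples x DEG features) and rank genes.

    Each tree is grown on a bootstrap sample with ``floor(sqrt(p))`` candidate
    features per split (classification defaults of the classical R
    implementation). Importance is the OOB permutation importance; with
    ``scaled=True`` it is divided by its standard error over trees.
    Deterministic given ``seed``.
    """
    if expr.n_genes < 2:
        raise ValueError("need >= 2 genes to rank")
    pheno = pheno.aligned_to(expr.sample_ids)
    y = np.array([1 if r == RESPONDER else 0 for r in pheno.response])
    if y.sum() < 2 or (len(y) - y.sum()) < 2:
        raise ValueError("need >= 2 samples per class")
    X = expr.values.T  # samples x genes
    n, p = X.shape
    rng = np.random.default_rng(seed)

    drops = np.zeros((n_trees, p))
    has_oob = np.zeros(n_trees, dtype=bool)
    for t in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(rng.integers(0, 2**31 - 1))
        )
        tree.fit(X[boot], y[boot])
        if oob.size == 0:
            continue
        has_oob[t] = True
        X_oob, y_oob = X[oob], y[oob]
        base_acc = np.mean(tree.predict(X_oob) == y_oob)
        for j in range(p):
            X_perm = X_oob.copy()
            X_perm[:, j] = X_perm[rng.permutation(oob.size), j]
            drops[t, j] = base_acc - np.mean(tree.predict(X_perm) == y_oob)

    used = drops[has_oob]
    importance = used.mean(axis=0)
    if scaled:
        se = used.std(axis=0, ddof=1) / np.sqrt(used.shape[0])
        importance = np.divide(
            importance, se, out=np.zeros_like(importance), where=se > 0
        )

    order = sorted(range(p), key=lambda i: (-importance[i], expr.gene_ids[i]))
    return RankedGeneList(
        gene_ids=[expr.gene_ids[i] for i in order],
        importances=importance[order],
        ranks=list(range(1, p + 1)),
        n_trees=n_trees,
        seed=seed,
    )


def top_k(ranked: RankedGeneList, k: int = 30) -> list[str]:
    """First ``k`` genes in rank order (the selected signature)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if k > len(ranked):
        raise ValueError(
            f"k={k} exceeds the {len(ranked)} ranked genes; lower k or relax "
            "the DEG filter thresholds"
        )
    return ranked.gene_ids[:k]
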