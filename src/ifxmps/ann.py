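"""One-hidden-layer neural network and the "Gene Weight" extraction.

Architecture: input = the binary Gene Score vector (one unit per signature
gene), one hidden layer of 10 ReLU units, output = two softmax units
(responder / non-responder). Loss is the mean categorical cross-entropy;
optimisation is full-batch Adam. After training, each gene's "Gene Weight"
is the (signed) maximum of its 10 input-to-hidden connection weights; an
absolute-maximum variant is available via a flag.

The forward/backward passes and the Adam update are implemented from their
mathematical definitions — no framework — so that the analytic gradients can
be checked against central finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GeneWeightTable
from .scoring import GeneScoreTable

__all__ = [
    "ANNHyperparams",
    "ANNModel",
    "init_params",
    "loss_and_gradients",
    "train_ann",
    "extract_gene_weights",
    "predict_proba",
]

N_HIDDEN = 10
N_CLASSES = 2

PARAM_NAMES = ("W_in", "b_hidden", "W_out", "b_out")


@dataclass
class ANNHyperparams:
    """Training settings; Adam moment/stability constants at their standard values."""

    learning_rate: float = 0.001
    epochs: int = 2000
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    n_hidden: int = N_HIDDEN
    init: str = "he_uniform"


@dataclass
class ANNModel:
    W_in: np.ndarray  # n_genes x n_hidden
    b_hidden: np.ndarray
    W_out: np.ndarray  # n_hidden x 2
    b_out: np.ndarray
    training_trace: list[float] = field(default_factory=list)
    hyperparams: ANNHyperparams = field(default_factory=ANNHyperparams)
    seed: int = 0

    def params(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in PARAM_NAMES}


def init_params(n_genes: int, n_hidden: int = N_HIDDEN, seed: int = 0) -> dict[str, np.ndarray]:
    """He-uniform weight initialisation (limit sqrt(6/fan_in)); zero biases."""
    rng = np.random.default_rng(seed)
    lim_in = np.sqrt(6.0 / n_genes)
    lim_out = np.sqrt(6.0 / n_hidden)
    return {
        "W_in": rng.uniform(-lim_in, lim_in, size=(n_genes, n_hidden)),
        "b_hidden": np.zeros(n_hidden),
        "W_out": rng.uniform(-lim_out, lim_out, size=(n_hidden, N_CLASSES)),
        "b_out": np.zeros(N_CLASSES),
    }


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def predict_proba(params: dict[str, np.ndarray], X: np.ndarray) -> np.ndarray:
    """Class probabilities (columns: non-responder, responder)."""
    hidden = np.maximum(X @ params["W_in"] + params["b_hidden"], 0.0)
    return _softmax(hidden @ params["W_out"] + params["b_out"])


def loss_and_gradients(
    params: dict[str, np.ndarray], X: np.ndarray, y: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean cross-entropy loss and its analytic gradients.

    X: samples x genes (the Gene Score matrix as floats); y: 0/1 class labels
    (1 = responder). Backprop through softmax + cross-entropy collapses to
    (probabilities - one-hot)/n at the logits.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = X.shape[0]
    pre = X @ params["W_in"] + params["b_hidden"]
    hidden = np.maximum(pre, 0.0)
    probs = _softmax(hidden @ params["W_out"] + params["b_out"])
    onehot = np.zeros_like(probs)
    onehot[np.arange(n), y] = 1.0
    # clip only inside the log; gradients use the exact probabilities
    loss = float(-np.mean(np.log(np.clip(probs[np.arange(n), y], 1e-300, None))))

    dlogits = (probs - onehot) / n
    dW_out = hidden.T @ dlogits
    db_out = dlogits.sum(axis=0)
    dhidden = dlogits @ params["W_out"].T
    dpre = dhidden * (pre > 0)
    grads = {
        "W_in": X.T @ dpre,
        "b_hidden": dpre.sum(axis=0),
        "W_out": dW_out,
        "b_out": db_out,
    }
    return loss, grads


def train_ann(
    table: GeneScoreTable,
    hyperparams: ANNHyperparams | None = None,
    seed: int = 0,
) -> ANNModel:
    """Train on a Gene Score table with full-batch Adam; deterministic given seed.

    ``training_trace`` records the loss at the start of every epoch (the value
    the epoch's gradient step is computed from). Both classes must be present:
    with one class the cross-entropy has no discriminative minimum for this
    two-output design.
    """
    hp = hyperparams or ANNHyperparams()
    y = table.response
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both responders and non-responders")
    X = table.scores.astype(float)
    params = init_params(X.shape[1], hp.n_hidden, seed)

    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(p) for k, p in params.items()}
    trace: list[float] = []
    for step in range(1, hp.epochs + 1):
        loss, grads = loss_and_gradients(params, X, y)
        trace.append(loss)
        for k in params:
            m[k] = hp.beta1 * m[k] + (1 - hp.beta1) * grads[k]
            v[k] = hp.beta2 * v[k] + (1 - hp.beta2) * grads[k] ** 2
            m_hat = m[k] / (1 - hp.beta1**step)
            v_hat = v[k] / (1 - hp.beta2**step)
            params[k] = params[k] - hp.learning_rate * m_hat / (np.sqrt(v_hat) + hp.eps)

    model = ANNModel(
        W_in=params["W_in"],
        b_hidden=params["b_hidden"],
        W_out=params["W_out"],
        b_out=params["b_out"],
        training_trace=trace,
        hyperparams=hp,
        seed=seed,
    )
    for name in PARAM_NAMES:
        if not np.all(np.isfinite(getattr(model, name))):
            raise RuntimeError(f"non-finite parameters in {name} after training")
    return model


def extract_gene_weights(
    model: ANNModel,
    gene_ids: list[str],
    directions: list[str],
    abs_max: bool = False,
) -> GeneWeightTable:
    """Per-gene "Gene Weight": the maximum input-to-hidden weight of that gene.

    The signed maximum over the 10 hidden units is the default; ``abs_max``
    selects the entry of largest magnitude instead (keeping its sign).
    Directions are carried through from the signature unchanged.
    """
    if model.W_in.shape[0] != len(gene_ids) or len(gene_ids) != len(directions):
        raise ValueError(
            f"W_in has {model.W_in.shape[0]} gene rows but {len(gene_ids)} "
            f"gene ids / {len(directions)} directions were given"
        )
    if abs_max:
        idx = np.argmax(np.abs(model.W_in), axis=1)
        weights = model.W_in[np.arange(len(gene_ids)), idx]
    else:
        weights = model.W_in.max(axis=1)
    return GeneWeightTable(list(gene_ids), weights, list(directions))
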