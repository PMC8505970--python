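"""Synthetic two-class expression cohorts with a planted response signature.

The generator emulates pooled baseline microarray cohorts of infliximab-treated
ulcerative-colitis patients: log2-scale intensities with additive Gaussian
noise, a planted 30-gene signature (mostly higher in non-responders), and
gene-constant additive batch offsets for the source datasets. It exists so
every downstream stage — batch removal, differential expression, random-forest
ranking, scoring, the neural network, and external validation — is testable
with known ground truth.

Model per gene g and sample s:

    value(g, s) = baseline(g) + class_effect(g, s) + batch_offset(batch(s)) + N(0, sigma^2)

where class_effect is +/- delta/2 depending on class and planted direction
(so the planted responder-minus-non-responder log2 fold change is exactly
+/- delta), and 0 for non-signature genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import NON_RESPONDER, RESPONDER, ExpressionMatrix, Phenotype

__all__ = ["SimConfig", "SignatureTruth", "simulate_cohort", "default_training_cohort_config"]


@dataclass
class SignatureTruth:
    """Planted signature genes and their directions relative to responders."""

    gene_ids: list[str]
    directions: list[str]  # "up" = higher in responders

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.gene_ids, self.directions))

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    delta is the planted |log2 fold change| (log2 units); sigma the
    within-class standard deviation. ``n_sig_down_in_resp`` genes are planted
    lower in responders (the published signature's analog is 28) and
    ``n_sig_up_in_resp`` higher (analog 2). ``batch_assignment`` maps each
    sample position (responders first, then non-responders) to a batch id.
    """

    n_genes: int = 1000
    n_sig_down_in_resp: int = 28
    n_sig_up_in_resp: int = 2
    n_resp: int = 23
    n_nonresp: int = 23
    delta: float = 2.0
    sigma: float = 0.5
    batch_offsets: dict[str, float] = field(default_factory=lambda: {"batch1": 0.0})
    batch_assignment: list[str] | None = None
    baseline_mean_range: tuple[float, float] = (4.0, 12.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_sig_down_in_resp, self.n_sig_up_in_resp,
               self.n_resp, self.n_nonresp) < 0:
            raise ValueError("all counts must be >= 0")
        if self.n_sig_down_in_resp + self.n_sig_up_in_resp > self.n_genes:
            raise ValueError("signature larger than the gene universe")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        lo, hi = self.baseline_mean_range
        if hi < lo:
            raise ValueError("baseline_mean_range must be (low, high)")
        n = self.n_resp + self.n_nonresp
        if self.batch_assignment is None:
            batches = list(self.batch_offsets)
            self.batch_assignment = [batches[0]] * n if batches else []
        if len(self.batch_assignment) != n:
            raise ValueError(
                f"batch_assignment has {len(self.batch_assignment)} entries "
                f"for {n} samples"
            )
        unknown = sorted(set(self.batch_assignment) - set(self.batch_offsets))
        if unknown:
            raise ValueError(f"batches without an offset: {unknown}")

    @property
    def n_samples(self) -> int:
        return self.n_resp + self.n_nonresp

    @property
    def n_signature(self) -> int:
        return self.n_sig_down_in_resp + self.n_sig_up_in_resp


def default_training_cohort_config(seed: int = 0) -> SimConfig:
    """Configuration mirroring the pooled two-dataset training cohort.

    46 samples (20 responders, 26 non-responders) in two batches of 24 and 22
    whose class composition follows the source datasets (8+16 and 12+10), a
    planted 30-gene signature (28 down / 2 up in responders) with delta=1.5 —
    above the |log2FC| > 1 screening threshold — and sigma=0.5.
    """
    # responders listed first: 8 from batch1, 12 from batch2; then
    # non-responders: 16 from batch1, 10 from batch2 (24 + 22 overall)
    assignment = (["batch1"] * 8 + ["batch2"] * 12 + ["batch1"] * 16 + ["batch2"] * 10)
    return SimConfig(
        n_genes=1000,
        n_sig_down_in_resp=28,
        n_sig_up_in_resp=2,
        n_resp=20,
        n_nonresp=26,
        delta=1.5,
        sigma=0.5,
        batch_offsets={"batch1": 0.0, "batch2": 0.8},
        batch_assignment=assignment,
        seed=seed,
    )


def simulate_cohort(config: SimConfig) -> tuple[ExpressionMatrix, Phenotype, SignatureTruth]:
    """Draw one cohort; identical configs (same seed) give bit-identical output.

    Returns the expression matrix, the phenotype table (with batch ids), and
    the planted truth. Signature genes are named ``SIG_DOWN_*`` / ``SIG_UP_*``
    and placed first; the remaining genes (``NULL_*``) carry no class effect.
    """
    rng = np.random.default_rng(config.seed)
    n_dn, n_up = config.n_sig_down_in_resp, config.n_sig_up_in_resp
    gene_ids = (
        [f"SIG_DOWN_{i+1:03d}" for i in range(n_dn)]
        + [f"SIG_UP_{i+1:03d}" for i in range(n_up)]
        + [f"NULL_{i+1:05d}" for i in range(config.n_genes - n_dn - n_up)]
    )
    sample_ids = [f"R{i+1:03d}" for i in range(config.n_resp)] + [
        f"N{i+1:03d}" for i in range(config.n_nonresp)
    ]
    response = [RESPONDER] * config.n_resp + [NON_RESPONDER] * config.n_nonresp

    lo, hi = config.baseline_mean_range
    baseline = rng.uniform(lo, hi, size=config.n_genes)

    # class effect: +/- delta/2 so that responder-minus-non-responder lfc = +/- delta
    sig_sign = np.zeros(config.n_genes)
    sig_sign[:n_dn] = -1.0  # lower in responders
    sig_sign[n_dn : n_dn + n_up] = +1.0
    is_resp = np.array([r == RESPONDER for r in response], dtype=float)
    class_effect = np.outer(sig_sign * config.delta / 2.0, 2.0 * is_resp - 1.0)

    offsets = np.array([config.batch_offsets[b] for b in config.batch_assignment])
    noise = rng.normal(0.0, config.sigma, size=(config.n_genes, config.n_samples))
    values = baseline[:, None] + class_effect + offsets[None, :] + noise

    expr = ExpressionMatrix(gene_ids, sample_ids, values)
    pheno = Phenotype(sample_ids, response, list(config.batch_assignment))
    truth = SignatureTruth(
        gene_ids[: n_dn + n_up], ["down"] * n_dn + ["up"] * n_up
    )
    return expr, pheno, truth
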