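import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from ifxmps import (
    ExpressionMatrix,
    Phenotype,
    SimConfig,
    load_published_weights,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def published_weights():
    return load_published_weights()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cohort():
    """46-sample, 200-gene single-batch cohort with a strong planted signature."""
    cfg = SimConfig(
        n_genes=200, n_sig_down_in_resp=28, n_sig_up_in_resp=2,
        n_resp=23, n_nonresp=23, delta=2.0, sigma=0.5, seed=11,
    )
    return simulate_cohort(cfg)


def make_expression(values, prefix_gene="G", prefix_sample="S") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        [f"{prefix_gene}{i+1}" for i in range(values.shape[0])],
        [f"{prefix_sample}{j+1}" for j in range(values.shape[1])],
        values,
    )


def make_phenotype(n_resp, n_nonresp, batch="b1") -> Phenotype:
    n = n_resp + n_nonresp
    return Phenotype(
        [f"S{j+1}" for j in range(n)],
        ["responder"] * n_resp + ["non_responder"] * n_nonresp,
        [batch] * n,
    )
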