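import logging

import numpy as np
import pytest

from netcog import synth

logging.getLogger("netcog").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def toy_adjacency():
    """4-node graph, networks A={1,2}, B={3,4}: w12=0.8, w34=0.6,
    w13=0.2, w24=0.4."""
    w = np.zeros((4, 4))
    w[0, 1] = w[1, 0] = 0.8
    w[2, 3] = w[3, 2] = 0.6
    w[0, 2] = w[2, 0] = 0.2
    w[1, 3] = w[3, 1] = 0.4
    return w


@pytest.fixture(scope="session")
def toy_partition():
    return synth.make_parcellation(4, 2)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small but fully structured cohort for integration-style tests."""
    parc = synth.make_parcellation(12, 3)
    spec = synth.CohortSpec(
        n_subjects=40, timepoints=120, segregation_sd=0.05, effect_beta=0.5, seed=7
    )
    return synth.generate_cohort(parc, spec)


def exact_correlation_data(R: np.ndarray, n: int, seed: int = 0) -> np.ndarray:
    """Data whose sample correlation matrix equals R exactly: orthonormalized
    noise columns pushed through the Cholesky factor."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, R.shape[0]))
    X -= X.mean(axis=0)
    Q, _ = np.linalg.qr(X)
    L = np.linalg.cholesky(R)
    Y = Q @ L.T
    return (Y - Y.mean(axis=0)) / Y.std(axis=0)
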