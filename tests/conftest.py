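import numpy as np
import pytest

import sleepnets as sn


@pytest.fixture(scope="session")
def study_cohort():
    """One study-like synthetic cohort (414 x 12), shared across tests."""
    return sn.generate_study_like_cohort(seed=123)


@pytest.fixture(scope="session")
def pair_params():
    """2-node Ising model with W_12 = ln 2: closed-form distribution
    (1/5, 1/5, 1/5, 2/5) over (00, 01, 10, 11)."""
    W = np.array([[0.0, np.log(2)], [np.log(2), 0.0]])
    return sn.IsingParameters(("x1", "x2"), np.zeros(2), W)


@pytest.fixture(scope="session")
def chain_spec():
    """3-node Bayesian-network chain A -> B -> C with strong CPTs."""
    return sn.BayesNetSpec(
        ("A", "B", "C"), ((), (0,), (1,)),
        ([0.5], [0.1, 0.9], [0.1, 0.9]))


@pytest.fixture()
def strong_pair_cohort():
    """n=1000 sample from a 3-item model with one planted strong edge."""
    W = np.zeros((3, 3))
    W[0, 1] = W[1, 0] = 2.0
    params = sn.IsingParameters(("a", "b", "c"), np.zeros(3), W)
    return sn.gibbs_sample_ising(params, 1000, seed=5)
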