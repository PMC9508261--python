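import numpy as np
import pandas as pd
import pytest

from hubdegree import CohortModel, simulate_cohort


@pytest.fixture
def hand_matrix():
    """4-parcel matrix with hand-computable degrees.

    w(1,2)=0.9, w(1,3)=0.8, w(1,4)=0.7, w(2,3)=0.3, w(2,4)=0.2, w(3,4)=0.1.
    """
    C = np.zeros((4, 4))
    for i, j, w in [(0, 1, 0.9), (0, 2, 0.8), (0, 3, 0.7),
                    (1, 2, 0.3), (1, 3, 0.2), (2, 3, 0.1)]:
        C[i, j] = C[j, i] = w
    return C


@pytest.fixture(scope="session")
def small_model():
    """A compact cohort model with planted hub and coupling effects."""
    sizes = {"DMN": 6, "VAN": 6, "FPN": 5, "UA": 5}
    return CohortModel(
        n_controls=8,
        n_patients=8,
        network_sizes=sizes,
        n_volumes=80,
        hub_parcels=(1, 7),
        group_delta=0.10,
        coupling_parcels=(8,),
        beta=0.3,
        sigma_y=3.0,
    )


@pytest.fixture(scope="session")
def small_cohort(small_model):
    return simulate_cohort(small_model, seed=1234)


def random_symmetric_matrix(rng, n, zero_prob=0.1, allow_ties=False):
    """Random nonnegative symmetric zero-diagonal matrix for oracle tests."""
    if allow_ties:
        vals = rng.choice([0.0, 0.1, 0.2, 0.3], size=(n, n))
    else:
        vals = rng.random((n, n))
        vals[rng.random((n, n)) < zero_prob] = 0.0
    C = np.triu(vals, k=1)
    return C + C.T
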