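import numpy as np
import pytest

from connectoprs import CohortConfig, ConnectivityMatrix
from connectoprs.synthetic import generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(w, weighting="NS", pid="p0"):
    w = np.asarray(w, dtype=float)
    labels = tuple(f"n{i}" for i in range(w.shape[0]))
    return ConnectivityMatrix(w, labels, weighting, pid)


@pytest.fixture
def k4():
    """Complete unit-weight graph on 4 nodes."""
    w = np.ones((4, 4)) - np.eye(4)
    return make_matrix(w)


@pytest.fixture
def p3():
    """Path graph A-B-C with unit weights."""
    w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    return make_matrix(w)


@pytest.fixture(scope="session")
def small_cohort():
    """A small shared cohort (12 participants, 90 nodes) for pipeline tests."""
    return generate_cohort(CohortConfig(n_participants=12, seed=7))
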