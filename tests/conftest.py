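import numpy as np
import pytest

from netsweep import (
    BinaryGraph,
    CohortSpec,
    ConnectivityMatrix,
    simulate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def graph_from_edges(n, edges):
    """Binary graph from an explicit edge list (test helper)."""
    a = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return BinaryGraph(a, 0.5)


def random_fc(n, rng, subject_id="sub-test"):
    """Random symmetric weight matrix in [-1, 1] with zero diagonal."""
    w = rng.uniform(-1, 1, size=(n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(subject_id, w)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 10-subject cohort (30 ROIs, 80 volumes) for pipeline tests."""
    spec = CohortSpec(
        n_responders=5, n_nonresponders=5, n_rois=30, n_timepoints=80,
        n_modules=3, seed=77)
    return simulate_cohort(spec)
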