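import numpy as np
import pytest

from betaconn.construction import BinaryNetwork


def adjacency(n, edges):
    a = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return a


def network(n, edges, density=float("nan")):
    return BinaryNetwork(a=adjacency(n, edges), density=density)


@pytest.fixture
def triangle():
    return network(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def path3():
    return network(3, [(0, 1), (1, 2)])


@pytest.fixture
def star5():
    # center 0 with 4 leaves
    return network(5, [(0, i) for i in range(1, 5)])


@pytest.fixture
def cycle4():
    return network(4, [(0, 1), (1, 2), (2, 3), (3, 0)])


@pytest.fixture
def two_cliques():
    # two disconnected triangles
    return network(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])


def complete(n):
    return network(n, [(i, j) for i in range(n) for j in range(i + 1, n)])


@pytest.fixture
def small_truth():
    """A compact ground truth (40 nodes, 4 modules) for fast cohorts."""
    from betaconn.synthetic import GroundTruth

    return GroundTruth(
        partition=np.repeat(np.arange(4), 10),
        target_node=None,
        role_profile={},
        n_participants=4,
        n_trials=60,
        seed=7,
    )
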