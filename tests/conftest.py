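import numpy as np
import pytest

from dagbayes import DAGHierarchy, compute_costs, random_dag


@pytest.fixture
def chain():
    return DAGHierarchy(3, ((0, 1), (1, 2)))


@pytest.fixture
def diamond():
    return DAGHierarchy(4, ((0, 1), (0, 2), (1, 3), (2, 3)))


@pytest.fixture
def chain_probs():
    return np.array([1.0, 0.8, 0.3])


def random_tree(n, seed):
    return random_dag(n, extra_edge_prob=0.0, seed=seed)


def random_chain_probs(n, rng):
    """Non-increasing marginals on a chain of length n (root = 1)."""
    p = np.ones(n)
    for i in range(1, n):
        p[i] = p[i - 1] * rng.uniform(0.05, 1.0)
    return p


def make_chain(n):
    return DAGHierarchy(n, tuple((i, i + 1) for i in range(n - 1)))


@pytest.fixture
def unit_costs_chain(chain):
    return compute_costs(chain)
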