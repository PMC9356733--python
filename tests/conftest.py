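import numpy as np
import pytest

from dynrecon.network import MultilayerNetwork, WindowScheme
from dynrecon.partition import NodePartition, demo_partition


def two_clique_layer():
    """6-node adjacency: two disjoint 3-cliques with unit weights."""
    A = np.zeros((6, 6))
    for group in ((0, 1, 2), (3, 4, 5)):
        for i in group:
            for j in group:
                if i != j:
                    A[i, j] = 1.0
    return A


@pytest.fixture
def clique_layer():
    return two_clique_layer()


@pytest.fixture
def clique_net():
    """Two disjoint 3-cliques replicated over 3 layers."""
    A = two_clique_layer()
    return MultilayerNetwork(layers=np.stack([A, A, A]))


@pytest.fixture
def clique_partition():
    ids = tuple(f"n{i}" for i in range(6))
    network_of = {ids[i]: ("left" if i < 3 else "right") for i in range(6)}
    return NodePartition(node_ids=ids, network_of=network_of)


@pytest.fixture
def planted_labels():
    """The planted 2-community assignment of the clique toy, over 3 layers."""
    return np.tile(np.array([1, 1, 1, 2, 2, 2]), (3, 1))


@pytest.fixture
def part9():
    return demo_partition(2)


def random_multilayer(rng, K, L, density=0.7):
    """Random symmetric nonnegative multilayer net with a connected union."""
    layers = np.empty((L, K, K))
    for l in range(L):
        W = rng.uniform(0.0, 1.0, (K, K))
        mask = rng.random((K, K)) < density
        A = np.triu(W * mask, 1)
        A = A + A.T
        # ensure every node touches at least one edge (ring fallback)
        for i in range(K):
            if A[i].sum() == 0.0:
                j = (i + 1) % K
                A[i, j] = A[j, i] = rng.uniform(0.2, 1.0)
        layers[l] = A
    return MultilayerNetwork(layers=layers)
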