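import numpy as np
import pytest

from adgcn.graph import BrainGraph, adjacency_from_edges, build_adjacency
from adgcn.synthetic import generate_icosphere


def random_connected_graph(rng: np.random.Generator, n: int) -> BrainGraph:
    """Random binary symmetric adjacency, forced connected via a spanning path."""
    edges = [(i, i + 1) for i in range(n - 1)]
    extra = rng.integers(0, n, size=(max(n, 2), 2))
    edges += [(int(a), int(b)) for a, b in extra if a != b]
    return adjacency_from_edges(n, np.array(edges))


@pytest.fixture(scope="session")
def ico0():
    return generate_icosphere(0)


@pytest.fixture(scope="session")
def ico2():
    return generate_icosphere(2)


@pytest.fixture(scope="session")
def ico2_graph(ico2):
    return build_adjacency(ico2)
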