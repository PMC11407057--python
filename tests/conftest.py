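import numpy as np
import networkx as nx
import pytest

import latspec as ls


@pytest.fixture
def p2():
    return ls.reference_graph("path", 2)


@pytest.fixture
def p3():
    return ls.reference_graph("path", 3)


@pytest.fixture
def c6():
    return ls.reference_graph("cycle", 6)


@pytest.fixture
def star5():
    """K_{1,4}: hub plus four leaves."""
    return ls.reference_graph("star", 5)


def random_molecular_graph(rng: np.random.Generator, max_vertices: int = 40):
    """Seeded Erdos-Renyi graph wrapped as a MolecularGraph."""
    k = int(rng.integers(2, max_vertices + 1))
    p = float(rng.uniform(0.1, 0.6))
    g = nx.gnp_random_graph(k, p, seed=int(rng.integers(0, 2**31)))
    return ls.make_graph([(v, "X") for v in g.nodes], list(g.edges))
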