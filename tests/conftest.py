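import numpy as np
import pytest

from modprio import (
    AssociationSet,
    GeneGraph,
    ModuleSet,
    SynthConfig,
    build_network,
    generate,
)


@pytest.fixture
def path_graph() -> GeneGraph:
    """x - u - v - y: exactly one L3 path between x and y."""
    g = GeneGraph()
    for e in [("x", "u"), ("u", "v"), ("v", "y")]:
        g.add_edge(*e)
    return g


@pytest.fixture
def star_graph() -> GeneGraph:
    g = GeneGraph()
    for leaf in ("p", "q", "r"):
        g.add_edge("c", leaf)
    return g


@pytest.fixture
def toy_network():
    """Small heterogeneous network: 5 genes, 2 diseases, 1 module."""
    g = GeneGraph()
    for e in [("g1", "g2"), ("g2", "g3"), ("g3", "g4"), ("g1", "g3"), ("g4", "g5")]:
        g.add_edge(*e)
    assoc = AssociationSet({("d1", "g1"), ("d1", "g2"), ("d2", "g4")})
    modules = ModuleSet({"M1": {"g1", "g2", "g3"}})
    return build_network(g, assoc, modules)


@pytest.fixture(scope="session")
def small_instance():
    """A compact synthetic instance shared by the slower integration tests."""
    cfg = SynthConfig(
        n_genes=60,
        n_diseases=6,
        n_modules=4,
        module_size_min=6,
        module_size_max=10,
        assoc_per_disease=6,
        seed=7,
    )
    return generate(cfg)


def random_gene_graph(n: int, p: float, seed: int) -> tuple[GeneGraph, np.ndarray, list[str]]:
    """Seeded Erdos-Renyi gene graph plus its dense adjacency and node order."""
    rng = np.random.default_rng(seed)
    names = [f"n{i:02d}" for i in range(n)]
    A = np.zeros((n, n))
    g = GeneGraph(nodes=set(names))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(names[i], names[j])
                A[i, j] = A[j, i] = 1.0
    return g, A, names
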