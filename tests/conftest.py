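import numpy as np
import pytest

from topolink import SyntheticConfig, generate_synthetic, make_transductive_split


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_bipartite(seed, n_drugs=8, n_genes=15, n_edges=45, n_classes=2):
    """Small random planted graph used across structural tests."""
    cfg = SyntheticConfig(n_drugs=n_drugs, n_genes=n_genes, n_edges=n_edges,
                          n_classes=n_classes, label_noise=0.0, seed=seed)
    g, _ = generate_synthetic(cfg)
    return g


@pytest.fixture
def small_graph():
    return random_bipartite(seed=1)


@pytest.fixture(scope="session")
def planted_graph():
    """The desk-scale planted study graph: 50x200 nodes, 2,000 edges,
    2 classes from a 2x2 block rule, 5% label noise."""
    g, truth = generate_synthetic(SyntheticConfig(seed=0))
    return g, truth


@pytest.fixture(scope="session")
def planted_split(planted_graph):
    g, _ = planted_graph
    return make_transductive_split(g, seed=0)
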