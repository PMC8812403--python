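import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_expr(rng):
    """5 genes x 10 samples of positive expression values."""
    genes = [f"G{i}" for i in range(5)]
    samples = [f"S{i}" for i in range(10)]
    return pd.DataFrame(rng.lognormal(0.0, 0.5, size=(5, 10)),
                        index=genes, columns=samples)


@pytest.fixture
def random_graph_factory(rng):
    import networkx as nx

    def make(n_nodes=10, p=0.3, seed=None):
        local = np.random.default_rng(seed) if seed is not None else rng
        nodes = [f"N{i}" for i in range(n_nodes)]
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for i in range(n_nodes):
            for j in range(i + 1, n_nodes):
                if local.random() < p:
                    g.add_edge(nodes[i], nodes[j])
        return g

    return make
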