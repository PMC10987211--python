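import numpy as np
import pytest

from modgnn import ModuleConfig, parse_smiles, random_graph_fixture
from modgnn.gnn_layers import init_layer_params

CAFFEINE = "Cn1cnc2c1c(=O)n(C)c(=O)n2C"


@pytest.fixture
def caffeine():
    return parse_smiles(CAFFEINE)


@pytest.fixture
def rng():
    return np.random.default_rng(20240313)


@pytest.fixture
def small_graph():
    """A fixed connected 6-node fixture graph."""
    return random_graph_fixture(6, edge_prob=0.4, seed=11)


def make_state(graph, d, seed=0):
    """Random node/edge embedding matrices of hidden width d for a graph."""
    r = np.random.default_rng(seed)
    return r.normal(size=(graph.n_atoms, d)), r.normal(size=(graph.n_edges, d))


def layer_params(config_bits, d, seed=0, zero=False):
    cfg = ModuleConfig(*config_bits)
    params = init_layer_params(np.random.default_rng(seed), d, cfg)
    if zero:
        for t in params.values():
            t.data = np.zeros_like(t.data)
    return cfg, params
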