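import numpy as np
import pytest

from redoxsolv.chemgraph import featurize
from redoxsolv.mpnn import ModelConfig, RedoxMPNN


@pytest.fixture(scope="session")
def small_sd_model():
    """A tiny untrained SD model shared by contract tests."""
    return RedoxMPNN(ModelConfig(variant="SD", node_dim=16, edge_dim=16,
                                 graph_dim=32, n_attention_heads=2,
                                 head_hidden=16, solvent_dim=4, seed=42))


@pytest.fixture(scope="session")
def small_vs_model():
    return RedoxMPNN(ModelConfig(variant="VS", node_dim=16, edge_dim=16,
                                 graph_dim=32, n_attention_heads=2,
                                 head_hidden=16, seed=42))


@pytest.fixture(scope="session")
def benzene():
    return featurize("c1ccccc1")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
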