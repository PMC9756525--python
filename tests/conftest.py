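import numpy as np
import pytest

from cpinet.fixtures import FixtureSpec, gen_dataset_in_memory
from cpinet.model import CPIModel, ModelConfig


def zero_parameters(model_or_component) -> None:
    """Set every parameter of a model/encoder/featurizer to zero."""
    for p in model_or_component.parameters():
        p.data = np.zeros_like(p.data)


@pytest.fixture(scope="session")
def small_dataset():
    """A tiny in-memory dataset (low embedding width for speed)."""
    spec = FixtureSpec(n_pairs=6, d0=32, protein_length_range=(12, 20),
                       seed=42)
    records, proteins, classes = gen_dataset_in_memory(spec)
    return records, proteins, classes


@pytest.fixture()
def micro_model():
    """A micro-scale model for closed-form and gradient tests."""
    return CPIModel(ModelConfig(d0=6, d1=4, n_conv_layers=2, gnn_layers=1,
                                kernel_size=3, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
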