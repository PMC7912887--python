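import numpy as np
import pytest

from mirtarnet.codec import MIRAW_SCHEMA
from mirtarnet.model import (
    ConvLayerSpec,
    ModelSpec,
    PoolSpec,
    RecurrentLayerSpec,
)
from mirtarnet.synth import SynthConfig, as_labeled_pairs, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_spec():
    """A scaled-down architecture for fast training tests."""
    return ModelSpec(
        input_len=MIRAW_SCHEMA.total_len,
        conv=ConvLayerSpec(n_kernels=32, kernel_size=8),
        pool=PoolSpec(2, 2),
        rnn=RecurrentLayerSpec(hidden_units=16),
        dense_hidden_units=8,
        dropout_rate=0.2,
    )


@pytest.fixture(scope="session")
def small_synth_dataset():
    """600 planted-seed pairs (miRAW-style 40-nt sites), session-cached."""
    cfg = SynthConfig(n_pos=300, n_neg=300, site_len=40, n_mirnas=8, rng_seed=42)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_synth_pairs(small_synth_dataset):
    return as_labeled_pairs(small_synth_dataset)
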