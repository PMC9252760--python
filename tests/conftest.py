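import numpy as np
import pytest

from resprop import ModelConfig, ProteinRecord
from resprop.simdata import GeneratorConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """A very small CNN/biLSTM configuration for shape and gradient tests."""
    return ModelConfig(
        input_dim=20, cnn_channels=4, kernel_sizes=(5, 9), paddings=(2, 4),
        lstm_hidden=8, lstm_layers=2, fc_width=16, dropout_p=0.0, seed=7,
    )


@pytest.fixture
def tiny_transformer_config():
    return ModelConfig(
        input_dim=20, downstream="transformer", transformer_dim=16,
        transformer_heads=4, transformer_layers=2, fc_width=16,
        dropout_p=0.0, seed=7,
    )


def reduced_config(**overrides) -> ModelConfig:
    """The reduced training configuration used for learning tests: channels 8,
    kernels 9/17, hidden 64, fc 64, with a lighter dropout and a higher
    learning rate suited to a model this small."""
    base = dict(
        input_dim=20, cnn_channels=8, kernel_sizes=(9, 17), paddings=(4, 8),
        lstm_hidden=64, lstm_layers=2, fc_width=64, dropout_p=0.1,
        lr=1e-3, batch_size=15, patience=3, seed=0,
    )
    base.update(overrides)
    return ModelConfig(**base)


@pytest.fixture
def small_dataset():
    """Eight annotated synthetic sequences of length about 100."""
    return generate_dataset(GeneratorConfig(n_sequences=8, length_range=(90, 110), seed=0))


@pytest.fixture
def records():
    return [
        ProteinRecord("p1", "ACDEFGHIKLMNPQRSTVWY"),
        ProteinRecord("p2", "MKTAYIAKQRQISFVKSHFS"),
    ]
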