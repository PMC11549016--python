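import numpy as np
import pytest

from ac4cnet import NetworkConfig, SyntheticSpec, TrainConfig, generate_synthetic
from ac4cnet.network import DualPathClassifier


@pytest.fixture(scope="session")
def tiny_config() -> NetworkConfig:
    """A deliberately small architecture for fast graph-level tests."""
    return NetworkConfig(
        d_model=8, gru_hidden=6, heads=2, conv_channels=(3, 4, 5),
        classifier_hidden=7, dropout=0.0, k=2,
    )


@pytest.fixture(scope="session")
def tiny_records():
    spec = SyntheticSpec(n_pos=8, n_neg=8, length=21, motif_rate=0.4, seed=11)
    return generate_synthetic(spec)


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    return DualPathClassifier(tiny_config, seed=3)


@pytest.fixture(scope="session")
def trained_tiny(tiny_config, tiny_records):
    """One quickly trained model plus a held-out set, shared across tests."""
    from ac4cnet import train_fold

    train = tiny_records[:6] + tiny_records[8:14]
    val = tiny_records[6:8] + tiny_records[14:16]
    cfg = TrainConfig(epochs=2, batch_size=8, seed=5)
    model, metrics = train_fold(train, val, tiny_config, cfg, seed=5)
    return model, val, metrics
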