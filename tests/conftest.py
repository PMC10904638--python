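import numpy as np
import pytest

from ddifusion import SynthConfig, features_from_descriptors, generate
from ddifusion.pair_classifier import TrainConfig

#: fast training settings for functional tests (not the study conditions).
TINY_TRAIN = dict(
    batch_size=4096,
    epochs=8,
    learning_rate=5e-3,
    gcn_dims=(16, 8, 4),
    dnn_hidden=(16, 8),
    method="hadamard",
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_synth():
    """A 60-drug planted-cluster dataset shared by functional tests."""
    return generate(SynthConfig(n_drugs=60, n_clusters=3, n_descriptors=30, n_types=4, seed=7))


@pytest.fixture(scope="session")
def small_features(small_synth):
    return features_from_descriptors(small_synth.descriptors)


@pytest.fixture
def tiny_binary_cfg():
    return TrainConfig(task="binary", seed=5, k=5, **TINY_TRAIN)


@pytest.fixture
def tiny_multiclass_cfg():
    return TrainConfig(task="multiclass", seed=5, k=5, **TINY_TRAIN)
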