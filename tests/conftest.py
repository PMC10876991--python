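import numpy as np
import pytest

from sscnova import AnnotationMatrix, ArchitectureSpec, SimulationConfig, TrainConfig


@pytest.fixture
def tiny_spec():
    """A miniature architecture for fast training in tests."""
    return ArchitectureSpec(
        input_len=20, conv1_kernel=3, conv1_filters=4, pool1=2,
        conv2_kernel=3, conv2_filters=6, pool2=2, dense_units=8,
        dropout_p=0.1,
    )


@pytest.fixture
def fast_cfg():
    return TrainConfig(epochs=3, batch_size=16, seed=0)


def make_matrix(n_pos, n_neg, n_features=20, n_informative=4, effect=3.0, seed=0):
    cfg = SimulationConfig(
        n_pos=n_pos, n_neg=n_neg, n_features=n_features,
        n_informative=n_informative, effect=effect, seed=seed,
    )
    from sscnova import simulate_annotation_dataset

    return simulate_annotation_dataset(cfg)


@pytest.fixture
def tiny_labeled():
    """60 variants, 20 features, 4 informative, strong effect."""
    return make_matrix(30, 30, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
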