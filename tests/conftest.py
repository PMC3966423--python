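import numpy as np
import pytest

from mldbn import MultiLabelDataset, RunConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_cfg():
    """Small hyperparameters for quick structural tests."""
    return RunConfig(
        layer_sizes=[6], batch_size=16, pretrain_epochs=3, finetune_epochs=3, seed=7
    )


@pytest.fixture
def small_dataset(rng):
    """Random valid 30x8 dataset with 3 labels."""
    X = (rng.random((30, 8)) < 0.4).astype(float)
    Y = (rng.random((30, 3)) < 0.5).astype(float)
    Y[0] = [1, 0, 1]  # guarantee at least one non-degenerate row
    return MultiLabelDataset(
        X, Y, [f"f{i}" for i in range(8)], ["a", "b", "c"]
    )


@pytest.fixture
def micro_example():
    """The hand-enumerated single instance: Q=3, relevant set {label 0}."""
    scores = np.array([[0.5, 0.9, 0.1]])
    Y = np.array([[1.0, 0.0, 0.0]])
    return scores, Y
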