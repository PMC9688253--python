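import numpy as np
import pytest

from jellyfuse import (
    ClassifierSpec,
    FeatureBlock,
    MultiViewDataset,
    SynthConfig,
    generate_dataset,
)


class FixedRng:
    """Stand-in random source returning a preset uniform value."""

    def __init__(self, u: float):
        self.u = float(u)

    def uniform(self, low=0.0, high=1.0, size=None):
        if size is None:
            return low + self.u * (high - low)
        return np.full(size, low + self.u * (high - low))

    def integers(self, *args, **kwargs):  # pragma: no cover - unused here
        raise NotImplementedError


@pytest.fixture
def fixed_rng():
    return FixedRng


@pytest.fixture
def toy_dataset():
    """Two tiny blocks over 12 samples, 2 balanced classes."""
    rng = np.random.default_rng(42)
    labels = np.array([0, 1] * 6)
    b1 = FeatureBlock("a", rng.normal(size=(12, 2)) + labels[:, None] * 3.0)
    b2 = FeatureBlock("b", rng.normal(size=(12, 3)))
    return MultiViewDataset([b1, b2], labels)


@pytest.fixture
def separable_dataset():
    """Well-separated 3-class synthetic data, small enough for fast fits."""
    config = SynthConfig(
        n_samples=150,
        n_classes=3,
        block_dims=(8, 8),
        informative_frac=(1.0, 1.0),
        effect_size=(6.0, 6.0),
        class_proportions=(1 / 3, 1 / 3, 1 / 3),
        seed=7,
    )
    return generate_dataset(config)


@pytest.fixture
def dt_spec():
    return ClassifierSpec("dt", seed=0)
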