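import numpy as np
import pytest

from confsel.datasets import LabeledDataset
from confsel.synth import GeneratorSpec, generate


@pytest.fixture
def tiny_dataset() -> LabeledDataset:
    """4 rows, 2 features, labels (0,0,1,0)."""
    return LabeledDataset(
        features=np.array([[0.0, 1.0], [1.0, 0.0], [5.0, 5.0], [0.5, 0.5]]),
        labels=np.array([0, 0, 1, 0]),
        feature_names=["a", "b"],
    )


@pytest.fixture
def separable_dataset() -> LabeledDataset:
    """Two well-separated 2-D Gaussian blobs, 3:1 imbalance."""
    rng = np.random.default_rng(7)
    n0, n1 = 150, 50
    X0 = rng.normal([-4.0, -4.0], 0.3, size=(n0, 2))
    X1 = rng.normal([4.0, 4.0], 0.3, size=(n1, 2))
    return LabeledDataset(
        features=np.vstack([X0, X1]),
        labels=np.r_[np.zeros(n0, int), np.ones(n1, int)],
    )


@pytest.fixture(scope="session")
def adora2a_like() -> LabeledDataset:
    """Synthetic table matching the 3:1 published shape: 2997 x 50, 850 ones."""
    return generate(GeneratorSpec(
        n_samples=2997, n_features=50, imbalance_ratio=3.0,
        minority_count=850, separation=1.5, seed=11,
    ))


@pytest.fixture(scope="session")
def oprk1_like() -> LabeledDataset:
    """Synthetic table matching the 20:1 published shape: 2999 x 50, 137 ones."""
    return generate(GeneratorSpec(
        n_samples=2999, n_features=50, imbalance_ratio=20.0,
        minority_count=137, separation=1.5, seed=13,
    ))
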