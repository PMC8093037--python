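import numpy as np
import pytest

from csnbstack import LabeledDataset, SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def separable_toy():
    """20 samples, 2 features, linearly separable, 1:3 imbalance."""
    rng = np.random.default_rng(7)
    n_pos, n_neg = 5, 15
    X = np.vstack(
        [
            rng.normal([5.0, 5.0], 0.3, size=(n_pos, 2)),
            rng.normal([-5.0, -5.0], 0.3, size=(n_neg, 2)),
        ]
    )
    labels = np.array(["tumor"] * n_pos + ["normal"] * n_neg)
    return LabeledDataset(X, labels)


@pytest.fixture
def small_imbalanced():
    """Synthetic 1:4 imbalanced dataset, modest effect, for classifier tests."""
    data, truth = generate(
        SyntheticSpec(
            n_samples=100, n_features=30, n_informative=8, n_redundant=4,
            imbalance=0.2, effect_size=1.5, seed=3,
        )
    )
    return data, truth
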