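import numpy as np
import pytest

from tnbayes import LabeledDataset, SyntheticSpec, estimate_model, generate_synthetic
from tnbayes.naive_bayes_core import ClassCounts, SmoothingParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_dataset():
    """3 compounds, 4 bits, 2 classes."""
    return LabeledDataset.from_string_labels(
        np.array([[1, 0, 1, 0], [1, 1, 0, 0], [0, 0, 1, 1]], dtype=np.uint8),
        ["A", "A", "B"],
        feature_names=("f1", "f2", "f3", "f4"),
        ids=("c1", "c2", "c3"),
    )


@pytest.fixture
def small_synthetic():
    spec = SyntheticSpec(
        J=3, L=40, n_per_class=30, n_informative=12, base_rate=0.1,
        signal_rate=0.5, block_size=1, block_corr=0.0, seed=11,
    )
    return generate_synthetic(spec)


def random_model(rng, n_classes=3, n_features=8, n_per_class=30, return_counts=False):
    """A valid fitted model from random counts (shared test helper)."""
    n_class = rng.integers(n_per_class, 2 * n_per_class, size=n_classes)
    n_present = np.stack([rng.integers(0, nc + 1, size=n_features) for nc in n_class])
    counts = ClassCounts(
        n_total=int(n_class.sum()),
        n_class=n_class.astype(np.int64),
        n_present=n_present.astype(np.int64),
        class_names=tuple(f"w{j}" for j in range(n_classes)),
    )
    model = estimate_model(counts, SmoothingParams.laplace(n_classes))
    return (model, counts) if return_counts else model


def conditional_rates(counts):
    """Laplace-smoothed p(x_l=1 | w_j) straight from the counts."""
    return (counts.n_present + 1.0) / (counts.n_class + 2.0)[:, None]
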