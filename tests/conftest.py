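import numpy as np
import pytest

from fuzzyrules.data import ExpressionDataset
from fuzzyrules.partitions import build_vocabulary


@pytest.fixture(scope="session")
def vocab():
    return build_vocabulary()


@pytest.fixture
def toy_dataset():
    """Three one-feature patterns: 0.0 -> class -1, 1.0 and 0.9 -> class 1."""
    return ExpressionDataset(
        values=np.array([[0.0], [1.0], [0.9]]),
        feature_names=["f1"],
        labels=np.array([-1, 1, 1]),
        normalized=True,
    )


@pytest.fixture
def random_dataset_factory():
    """Small random normalized datasets with both classes guaranteed."""

    def make(seed: int, m: int = 8, n: int = 3) -> ExpressionDataset:
        rng = np.random.default_rng(seed)
        labels = np.ones(m, dtype=int)
        labels[: m // 2] = -1
        rng.shuffle(labels)
        return ExpressionDataset(
            values=rng.random((m, n)),
            feature_names=[f"f{i}" for i in range(n)],
            labels=labels,
            normalized=True,
        )

    return make


def naive_masses(conditions, data, vocab):
    """Reference double-loop class compatibility masses (oracle path).

    Deliberately scalar and loop-based, independent of the vectorized
    implementation it checks.
    """
    pos = neg = 0.0
    for p in range(data.m):
        comp = 1.0
        for f, c in enumerate(conditions):
            comp *= vocab[c].membership(float(data.values[p, f]))
        if data.labels[p] == 1:
            pos += comp
        else:
            neg += comp
    return pos, neg
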