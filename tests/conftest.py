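import numpy as np
import pytest

from khknn import FeatureTable


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_two_class_table(rng, n_min=10, n_max=60, d_min=2, d_max=10):
    """A random two-class FeatureTable with both classes guaranteed >= 2 members."""
    n = int(rng.integers(n_min, n_max + 1))
    d = int(rng.integers(d_min, d_max + 1))
    values = rng.standard_normal((n, d))
    labels = rng.integers(0, 2, size=n)
    labels[:2] = 0
    labels[2:4] = 1
    return FeatureTable(
        values=values,
        feature_names=[f"f{j}" for j in range(d)],
        feature_kinds=["continuous"] * d,
        labels=labels,
    )


def table_1d(points0, points1):
    """Two-class 1-D table from explicit coordinate lists."""
    vals = np.array(list(points0) + list(points1), dtype=float)[:, None]
    labels = np.array([0] * len(points0) + [1] * len(points1))
    return FeatureTable(vals, ["x"], ["continuous"], labels)
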