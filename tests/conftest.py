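import numpy as np
import pytest

from recspot import FixtureSpec, generate
from recspot.classifier import COLDSPOT, HOTSPOT
from recspot.features import encode_many


@pytest.fixture(scope="session")
def separated_dataset():
    """GC-composition-separated two-class set (0.3 vs 0.7), n=30/class."""
    spec = FixtureSpec(
        n_per_class=30, length_range=(300, 3000), gc_hot=0.3, gc_cold=0.7, seed=7
    )
    seqs, labels = generate(spec)
    return seqs, labels


@pytest.fixture(scope="session")
def separated_features(separated_dataset):
    seqs, labels = separated_dataset
    return encode_many(seqs).to_numpy(), labels


@pytest.fixture(scope="session")
def blob_dataset():
    """Two well-separated Gaussian clusters in 69-dim feature space (seed 7).

    Linearly separable by construction: cluster centres differ by 4 units
    in every coordinate while the within-cluster spread is 0.3.
    """
    rng = np.random.default_rng(7)
    n = 20
    dim = 69
    hot = rng.normal(loc=2.0, scale=0.3, size=(n, dim))
    cold = rng.normal(loc=-2.0, scale=0.3, size=(n, dim))
    X = np.vstack([hot, cold])
    y = np.array([HOTSPOT] * n + [COLDSPOT] * n)
    return X, y
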