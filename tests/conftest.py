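import numpy as np
import pytest

from swarmfs import SyntheticSpec, generate_synthetic


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic diagnosis table (n=300, D=13, 4 informative)."""
    return generate_synthetic(SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def small_dataset():
    """A D=10 table small enough for exhaustive mask enumeration."""
    return generate_synthetic(SyntheticSpec(D=10, seed=0))


@pytest.fixture(scope="session")
def separable_toy():
    """A linearly separable two-class toy: 60 samples, 3 features."""
    rng = np.random.default_rng(42)
    n = 60
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, 3))
    X[:, 0] += 6.0 * y  # wide separation on one feature
    perm = rng.permutation(n)
    return X[perm], y[perm]
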