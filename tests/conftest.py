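import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_problem(rng):
    """A well-conditioned 30x6 regression instance with known weights."""
    X = rng.standard_normal((30, 6))
    w = np.array([1.5, -1.0, 0.0, 0.5, 0.0, -2.0])
    y = X @ w + 0.1 * rng.standard_normal(30)
    return X, y, w
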