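import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_chain(n, rng, jitter=0.05):
    """Random-walk chain with near-unit bonds (safe for the FENE term)."""
    steps = rng.normal(size=(n - 1, 3))
    steps /= np.linalg.norm(steps, axis=1)[:, None]
    x = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    x += rng.normal(0.0, jitter, size=x.shape)
    return x - x.mean(axis=0)


def random_alpha(n, rng, scale=3.0):
    """Symmetric restraint matrix, zero on the diagonal and bonded pairs."""
    a = np.zeros((n, n))
    iu = np.triu_indices(n, k=2)
    a[iu] = rng.normal(0.0, scale, iu[0].size)
    return a + a.T
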