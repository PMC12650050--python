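import numpy as np
import pytest

from teayolo.nn.module import seed_all


@pytest.fixture(autouse=True)
def _seed():
    seed_all(0)
    np.random.seed(0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def finite_difference_grad(f, x, eps=1e-5):
    """Central-difference gradient of scalar f at array x."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[i] += eps
        xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
        it.iternext()
    return g
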