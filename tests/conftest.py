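import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def numeric_gradient(f, x, eps=1e-6):
    """Central finite differences of scalar f() w.r.t. array x (mutated
    in place)."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g
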