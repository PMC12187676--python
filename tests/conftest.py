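import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hasaseg.nn import Tensor
from hasaseg.nn.tensor import using_dtype

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def f64():
    """Run the test body in float64 (oracle/finite-difference precision)."""
    with using_dtype(np.float64):
        yield


def numeric_gradient(fn, tensors, h=1e-6, n_samples=6, rng=None):
    """Central finite differences of a scalar-producing ``fn(*tensors)``
    against backprop; returns the worst relative error over sampled entries.
    """
    rng = rng or np.random.default_rng(0)
    for t in tensors:
        t.grad = None
    out = fn(*tensors)
    seed = rng.normal(size=out.shape)
    (out * Tensor(seed)).sum().backward()
    worst = 0.0
    for t in tensors:
        grad = t.grad
        flat = t.data.ravel()
        idxs = rng.choice(flat.size, size=min(n_samples, flat.size), replace=False)
        for i in idxs:
            orig = flat[i]
            flat[i] = orig + h
            lp = float((fn(*tensors).data * seed).sum())
            flat[i] = orig - h
            lm = float((fn(*tensors).data * seed).sum())
            flat[i] = orig
            fd = (lp - lm) / (2 * h)
            bp = grad.ravel()[i]
            worst = max(worst, abs(fd - bp) / max(abs(fd), abs(bp), 1e-8))
    return worst
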