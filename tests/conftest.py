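import numpy as np
import pytest

from ecgdet.autodiff import Tensor


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tensor(rng, shape, scale=1.0, requires_grad=False):
    t = Tensor(rng.standard_normal(shape) * scale)
    t.requires_grad = requires_grad
    return t


@pytest.fixture
def make_tensor(rng):
    def _make(shape, scale=1.0, requires_grad=False):
        return tensor(rng, shape, scale, requires_grad)
    return _make
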