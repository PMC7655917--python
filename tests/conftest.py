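import numpy as np
import pytest

from fsnet import nn
from fsnet.network import FsNetConfig
from fsnet.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_net_config():
    """Narrow cascade that keeps CPU tests fast; all stages >= 8 channels."""
    return FsNetConfig(channel_plan=(8, 16, 32, 64, 128), input_size=32,
                       fusion_widths=(8, 16, 32))


@pytest.fixture
def tiny_spec():
    return PhantomSpec(image_size=32, n_samples=12, slices_per_patient=2, seed=7)


@pytest.fixture
def tiny_pairs(tiny_spec):
    return [generate_phantom(tiny_spec, i) for i in range(tiny_spec.n_samples)]


def finite_difference(loss_fn, param_data, index, eps=1e-6):
    """Central finite difference of a scalar-valued callable at one entry."""
    old = param_data[index]
    param_data[index] = old + eps
    lp = loss_fn()
    param_data[index] = old - eps
    lm = loss_fn()
    param_data[index] = old
    return (lp - lm) / (2 * eps)


@pytest.fixture
def fd():
    return finite_difference


@pytest.fixture(autouse=True)
def _reset_param_rng():
    nn.manual_seed(0)
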