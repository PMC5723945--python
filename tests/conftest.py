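import numpy as np
import pytest

from entroseg import ModelParams, make_kernel


@pytest.fixture
def small_params():
    """Parameters sized for 8–16 pixel test instances."""
    return ModelParams(kernel_sigma=1.5, radius_r=3)


@pytest.fixture
def small_kernel(small_params):
    return make_kernel(small_params.kernel_sigma, small_params.radius)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
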