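import numpy as np
import pytest

from gfadwi import TensorSpec, build_phantom, make_scheme

SINGLE_FIBER = (1.7e-3, 0.2e-3, 0.2e-3)

#: closed-form FA of the canonical single fiber, evaluated by hand:
#: sqrt(1/2) * sqrt((1.5)^2 + 0 + (-1.5)^2) / sqrt(1.7^2 + 0.2^2 + 0.2^2)
SINGLE_FIBER_FA = float(np.sqrt(0.5 * (1.5**2 + 0.0 + 1.5**2) / (1.7**2 + 0.04 + 0.04)))


@pytest.fixture(scope="session")
def scheme21():
    return make_scheme(21, 1000.0)


@pytest.fixture(scope="session")
def noiseless_phantom(scheme21):
    """Default four-block phantom, no noise (session-scoped: read-only)."""
    return build_phantom((16, 16, 4), scheme21, sigma=0.0)


@pytest.fixture
def single_fiber_spec():
    return TensorSpec(SINGLE_FIBER, principal_direction=(1.0, 0.0, 0.0))
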