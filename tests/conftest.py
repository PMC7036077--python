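import numpy as np
import pytest

from scintibsi.nn import tensor as nn_tensor
from scintibsi.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def float64_engine():
    """Run the NN engine in float64 for finite-difference gradient checks."""
    old = nn_tensor.get_default_dtype()
    nn_tensor.set_default_dtype(np.float64)
    yield
    nn_tensor.set_default_dtype(old)


@pytest.fixture(scope="session")
def small_case():
    """One deterministic desk-scale phantom case shared across tests."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def noiseless_case():
    return generate_phantom(PhantomSpec(seed=7, noise_model="none"))
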