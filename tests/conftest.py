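import numpy as np
import pytest

from wmdamage import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Default noisy phantom (64 cubed, SNR 20, 8 lesions)."""
    spec = PhantomSpec(seed=7)
    scan, truth = generate_phantom(spec)
    return spec, scan, truth


@pytest.fixture(scope="session")
def noiseless_phantom():
    spec = PhantomSpec(noise_sd=0.0, seed=7)
    scan, truth = generate_phantom(spec)
    return spec, scan, truth


@pytest.fixture(scope="session")
def small_phantom():
    """Smaller noisy phantom for the slower clustering tests."""
    spec = PhantomSpec(grid_shape=(40, 40, 40), n_lesions=5, seed=11)
    scan, truth = generate_phantom(spec)
    return spec, scan, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
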