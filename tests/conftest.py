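import numpy as np
import pytest

from fermiperf.phantom import PhantomConfig, make_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless, motion-free phantom at default geometry (shared)."""
    cfg = PhantomConfig(noise_sd=0.0, motion_amplitude=0.0)
    return make_phantom(cfg)


@pytest.fixture(scope="session")
def small_clean_phantom():
    """Smaller, shorter noiseless phantom for fast registration tests."""
    cfg = PhantomConfig(noise_sd=0.0, motion_amplitude=0.0, n_frames=40)
    return make_phantom(cfg)


@pytest.fixture
def times():
    return np.arange(120) * 0.5
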