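import numpy as np
import pytest

from ringseg.synthetic import SynthConfig, generate_sample


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def float64_engine():
    """Run the autograd engine in float64 for finite-difference checks."""
    from ringseg.nn import autograd

    autograd.set_default_dtype(np.float64)
    yield
    autograd.set_default_dtype(np.float32)


@pytest.fixture(scope="session")
def small_synth_config():
    return SynthConfig(
        height_px=320,
        width_px=128,
        n_boundaries=2,
        mean_ring_width_px=100.0,
        ring_width_cv=0.1,
        boundary_waviness_px=3.0,
        fiber_band_halfwidth_px=3,
        vessels_per_ring_mean=8.0,
        vessel_radius_range_px=(3.0, 6.0),
        noise_sd=4.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_sample(small_synth_config):
    return generate_sample(small_synth_config)
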