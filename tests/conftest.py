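import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ifcdose.synthdata import SimulationParams

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


@pytest.fixture
def params():
    return SimulationParams()


@pytest.fixture
def noiseless_params():
    """All stochastic knobs off: exact affine MFI, exact saturating spots."""
    return SimulationParams(cell_noise_sd=0.0, sample_noise_sd=0.0, donor_sd=0.0, contaminant_fraction=0.0)


@pytest.fixture
def small_image_params():
    """Small rasters for image-heavy tests."""
    return SimulationParams(image_size=48, nucleus_radius=14, cells_per_sample=20)
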