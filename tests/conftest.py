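import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from smartscan import acquisition, phantom

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_scene():
    """Default osteon-ring phantom at the scaled-down study size."""
    return phantom.make_scene(32, 32, L=128, seed=1)


@pytest.fixture(scope="session")
def small_cube(small_scene):
    return phantom.render_cube(small_scene)


@pytest.fixture(scope="session")
def calibrated_noise(small_cube):
    """Noise model hitting the low/high SNR pair on the small phantom."""
    return acquisition.calibrate_noise_model(small_cube, seed=7)


@pytest.fixture(scope="session")
def sem_image(small_scene):
    return phantom.make_sem(small_scene, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
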