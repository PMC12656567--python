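import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from grassunmix.synthetic_scene import (
    DEFAULT_CLASSES,
    make_scene_truth,
    render_cube,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_truth():
    """Clean 24x24 scene, 120 bands, noiseless, no injected defects."""
    return make_scene_truth(
        rows=24,
        cols=24,
        n_bands=120,
        noise_sd=0.0,
        corrupted_band_ranges=(),
        n_nodata=0,
        n_negative=0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cube(small_truth):
    return render_cube(small_truth)


@pytest.fixture(scope="session")
def small_library(small_truth):
    return small_truth.library


@pytest.fixture(scope="session")
def noisy_truth():
    """40x40 scene with noise, corrupted water bands, and defect pixels."""
    return make_scene_truth(
        rows=40,
        cols=40,
        n_bands=426,
        noise_sd=0.01,
        n_nodata=4,
        n_negative=4,
        seed=23,
    )


@pytest.fixture(scope="session")
def noisy_cube(noisy_truth):
    return render_cube(noisy_truth)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(99)
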