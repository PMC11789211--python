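import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from canopybef import LandscapeConfig, generate_truth
from canopybef.spectral_indices import ReflectanceScene

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> LandscapeConfig:
    """A 48x48 landscape, 5 subregions, 3 August scenes per year: the same
    generative structure as the defaults at a size unit tests can afford."""
    return LandscapeConfig(rows=48, cols=48, n_subregions=5, n_august_dates=3)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_truth(small_config, seed=11)


@pytest.fixture(scope="session")
def noiseless_config() -> LandscapeConfig:
    return LandscapeConfig(
        rows=48, cols=48, n_subregions=5, n_august_dates=3,
        noise_sd_reflectance=0.0, noise_sd_ndwi=0.0,
        cloud_fraction=0.0, shadow_fraction=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_truth(noiseless_config):
    return generate_truth(noiseless_config, seed=5)


def constant_scene(shape=(4, 4), **overrides) -> ReflectanceScene:
    """Uniform reflectance scene with selected per-band values."""
    base = {
        "B2": 0.03, "B3": 0.10, "B4": 0.06, "B5": 0.08, "B6": 0.25,
        "B7": 0.16, "B8": 0.30, "B8A": 0.35, "B11": 0.12, "B12": 0.10,
    }
    base.update(overrides)
    return ReflectanceScene(
        {k: np.full(shape, float(v)) for k, v in base.items()}, 20.0, "test"
    )
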