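import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hepaseg import NoiseSpec, PhantomSpec, add_noise, generate_phantom
from hepaseg.se_resunet import ModelConfig

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def phantom_pair():
    """The fixture phantom: 256x256, seed 7."""
    return generate_phantom(PhantomSpec(), seed=7)


@pytest.fixture(scope="session")
def noisy_phantom(phantom_pair):
    """Fixture phantom with salt-and-pepper at density 0.02."""
    img, _ = phantom_pair
    return add_noise(img, NoiseSpec(mode="impulse", impulse_density=0.02,
                                    salt_vs_pepper=0.5, seed=7))


@pytest.fixture(scope="session")
def small_phantom_pair():
    """64x64 phantom for network-speed tests."""
    return generate_phantom(PhantomSpec(size=64), seed=7)


@pytest.fixture
def tiny_config():
    """Small network config for fast trainer tests."""
    return ModelConfig(base_width=8, se_ratio=4)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
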