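import numpy as np
import pytest

from flockgn import SimulationConfig
from flockgn.vicsek import ParticleConfiguration


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    return SimulationConfig(
        n_particles=100, box_side=5.0, speed=0.03, radius=1.0, noise=1.0, n_steps=20, seed=7
    )


def random_configuration(rng, n, box_side):
    return ParticleConfiguration(
        rng.uniform(0, box_side, size=(n, 2)), rng.uniform(-np.pi, np.pi, size=n)
    )


@pytest.fixture
def random_cfg(rng):
    return random_configuration(rng, 60, 8.0)
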