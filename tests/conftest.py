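import numpy as np
import pytest

from cerebromech.mechanics import RingGeometry
from cerebromech import synthetic


@pytest.fixture(scope="session")
def geometry():
    return RingGeometry.from_radii(R_o_um=1200.0, R_i_um=1000.0, unloaded_length_mm=10.0)


@pytest.fixture(scope="session")
def noise_free_cycle():
    """Analyzed depressurization limb of a noise-free simulated artery."""
    sim = synthetic.simulate_inflation(seed=0)
    return sim, sim.analyze()


@pytest.fixture(scope="session")
def fiber_scene():
    """Default synthetic fiber image (32 um gap), generated once."""
    return synthetic.generate_fiber_image(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
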