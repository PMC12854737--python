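import numpy as np
import pytest

from icedust.particle_size import ParticleSet
from icedust.synthetic import SyntheticSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20170601)


@pytest.fixture
def small_particles():
    return ParticleSet(diameters=np.array([1.0, 2.0, 3.0]), sample_id="toy")


@pytest.fixture
def default_spec():
    """Campaign-default synthetic spec with a short two-day time span."""
    return SyntheticSpec(seed=7, campaign_days=2)
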