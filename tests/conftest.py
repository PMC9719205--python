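import numpy as np
import pytest

from molardrift import GroundTruthMotion, PhantomSpec
from molardrift.phantom import ArchPhantom


@pytest.fixture
def default_spec():
    """Analysis-grade phantom: 0.25 mm voxels, intensity noise on."""
    return PhantomSpec()


@pytest.fixture
def coarse_spec():
    """Coarse, fast phantom for smoke-level pipeline tests."""
    return PhantomSpec(voxel_spacing_mm=(0.5, 0.5, 0.5))


@pytest.fixture
def clean_spec():
    """Noise-free phantom for voxel-exact assertions."""
    return PhantomSpec(noise_sd=0.0)


@pytest.fixture
def phantom(default_spec):
    return ArchPhantom(default_spec)


@pytest.fixture
def exact_landmarks(phantom):
    return phantom.landmarks()


@pytest.fixture
def zero_motion():
    return GroundTruthMotion.zero()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
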