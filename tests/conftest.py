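import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from voxelrad.detector import load_detector
from voxelrad.materials import load_material_tables
from voxelrad.phantom import make_slab, make_torso_surrogate
from voxelrad.spectrum import Spectrum

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tables():
    return load_material_tables()


@pytest.fixture(scope="session")
def kodak_dr():
    return load_detector("kodak_dr7500")


@pytest.fixture(scope="session")
def mono60():
    """Single-bin 57.5 keV probe spectrum (unit fluence)."""
    return Spectrum(60.0, np.array([57.5]), np.array([1.0]))


@pytest.fixture(scope="session")
def water_slab():
    """100 mm water slab, wide enough that oblique test rays stay inside."""
    return make_slab(material_hu=0.0, thickness_mm=100.0, lateral_mm=300.0, voxel_size_mm=1.0)


@pytest.fixture(scope="session")
def torso():
    return make_torso_surrogate()
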