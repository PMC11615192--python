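import numpy as np
import pytest

from paleoshell.hydrography import HydroProfile
from paleoshell.io_config import load_reference_tables
from paleoshell.synthetic import generate_phantom


@pytest.fixture(scope="session")
def ref():
    """Packaged 16-site reference tables (canonical units)."""
    return load_reference_tables()


@pytest.fixture()
def linear_profile():
    """T(z) = 28 − 0.1·z and S(z) = 37 − 0.01·z on the standard grid."""
    z = np.array([2.5] + list(range(10, 201, 10)) + list(range(220, 301, 20)), float)
    return HydroProfile(
        site_id=1,
        month="mean",
        depths=z,
        temperature=28.0 - 0.1 * z,
        salinity=37.0 - 0.01 * z,
    )


@pytest.fixture(scope="session")
def hollow_sphere():
    """Digitised hollow sphere R=50 μm, wall 10 μm, no aperture, 1.2 μm voxels."""
    return generate_phantom(50.0, 10.0, voxel_size=1.2)
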