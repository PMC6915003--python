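import numpy as np
import pytest

from acval import (
    MuMap,
    PhantomSpec,
    VoxelImage,
    default_geometry,
    make_body_phantom,
    make_cylinder_phantom,
)

SMALL_SHAPE = (64, 64)
SMALL_SPACING = (2.4, 2.4)
MID_SHAPE = (128, 128)


@pytest.fixture(scope="session")
def small_geom():
    return default_geometry(SMALL_SHAPE, SMALL_SPACING, n_angles=60)


@pytest.fixture(scope="session")
def mid_geom():
    return default_geometry(MID_SHAPE, SMALL_SPACING, n_angles=120)


@pytest.fixture(scope="session")
def small_disk():
    """Uniform disk of radius 60 mm, value 1, on the small grid."""
    img = VoxelImage(np.zeros(SMALL_SHAPE), SMALL_SPACING)
    Y, X = img.coord_grids()
    return img.copy_with((Y**2 + X**2 <= 60.0**2).astype(float))


@pytest.fixture(scope="session")
def cylinder_mid():
    """20 cm cylinder phantom (no hardware) on the 128 grid."""
    spec = PhantomSpec(kind="cylinder")
    return make_cylinder_phantom(spec, MID_SHAPE, SMALL_SPACING)


@pytest.fixture(scope="session")
def body_mid():
    spec = PhantomSpec(kind="body_slice", seed=7)
    return make_body_phantom(spec, MID_SHAPE, SMALL_SPACING)


@pytest.fixture(scope="session")
def mu_disk():
    """Water-equivalent uniform mu disk, radius 100 mm, on the 128 grid."""
    img = VoxelImage(np.zeros(MID_SHAPE), SMALL_SPACING)
    Y, X = img.coord_grids()
    mu = np.where(Y**2 + X**2 <= 100.0**2, 0.0096, 0.0)
    return MuMap(mu, SMALL_SPACING, provenance="custom")
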