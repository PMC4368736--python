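import numpy as np
import pytest

from nucmix import anatomy, grids, meta


@pytest.fixture(scope="session")
def default_cohort():
    """The default seeded 30-subject cohort (shared; ~seconds to build)."""
    return anatomy.generate_cohort(anatomy.default_config())


@pytest.fixture(scope="session")
def foci_records():
    return meta.load_foci()


@pytest.fixture()
def small_grid():
    return grids.make_grid(((-10.0, 10.0), (-10.0, 10.0), (-10.0, 10.0)), spacing=0.5)


def sphere_mask(grid, center, radius):
    """Voxelized sphere: voxel centers within ``radius`` of ``center``."""
    center = np.asarray(center, dtype=float)
    axes = [grid.axis_coords(d) for d in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    d2 = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 + (zz - center[2]) ** 2
    return grids.BinaryMask(grid=grid, data=(d2 <= radius**2).astype(np.uint8))


@pytest.fixture()
def sphere_mask_factory():
    return sphere_mask
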