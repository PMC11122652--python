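import numpy as np
import pytest

from ezquant.cube_model import CubeGeometry, SurfaceSet

SMALL_GEOMETRY = CubeGeometry(n_ascans=32, n_bscans=32, n_depth=256)


@pytest.fixture
def small_geometry() -> CubeGeometry:
    """32x32-column lattice over the standard 6x6 mm footprint."""
    return SMALL_GEOMETRY


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_surfaces(geometry: CubeGeometry, thickness_um=30.0,
                  ez_absent_mask=None, rpe_depth_um=300.0) -> SurfaceSet:
    """Flat surface stack with the given EZ-RPE thickness field."""
    shape = (geometry.n_bscans, geometry.n_ascans)
    t = np.broadcast_to(np.asarray(thickness_um, dtype=float), shape).copy()
    rpe = np.full(shape, rpe_depth_um)
    ez = rpe - t
    if ez_absent_mask is not None:
        ez[ez_absent_mask] = np.nan
    ilm = rpe - t - 120.0
    bm = rpe + 15.0
    return SurfaceSet(geometry=geometry, ilm=ilm, ez=ez, rpe=rpe, bm=bm)


@pytest.fixture
def make_flat_surfaces():
    return make_surfaces
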