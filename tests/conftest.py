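import numpy as np
import pytest

from segqa import BinaryMask, ImageGeometry


@pytest.fixture
def iso_geom():
    """Small isotropic 1 mm grid for metric tests."""
    return ImageGeometry(shape=(24, 24, 24), spacing=(1.0, 1.0, 1.0))


@pytest.fixture
def ct_geom():
    """Grid mirroring the 2.0 mm slice-thickness CT protocol."""
    return ImageGeometry(shape=(48, 48, 40), spacing=(1.0, 1.0, 2.0))


def ball_mask(geom: ImageGeometry, center, radius) -> BinaryMask:
    """Solid digitized sphere: voxel centers within radius (mm) of center (mm)."""
    xs = geom.axis_coords(0)[:, None, None]
    ys = geom.axis_coords(1)[None, :, None]
    zs = geom.axis_coords(2)[None, None, :]
    c = np.asarray(center, dtype=float)
    v = (xs - c[0]) ** 2 + (ys - c[1]) ** 2 + (zs - c[2]) ** 2 <= radius**2
    return BinaryMask(geom, v)


def box_mask(geom: ImageGeometry, lo_idx, hi_idx) -> BinaryMask:
    """Solid box by half-open voxel index ranges."""
    v = np.zeros(geom.shape, dtype=bool)
    v[lo_idx[0]:hi_idx[0], lo_idx[1]:hi_idx[1], lo_idx[2]:hi_idx[2]] = True
    return BinaryMask(geom, v)


def random_blob_mask(rng: np.random.Generator, geom: ImageGeometry) -> BinaryMask:
    """Union of 1-3 random balls; surfaces stay small enough for O(n^2) oracles."""
    v = np.zeros(geom.shape, dtype=bool)
    extent = (np.asarray(geom.shape) - 1) * np.asarray(geom.spacing)
    for _ in range(int(rng.integers(1, 4))):
        c = rng.uniform(0.2, 0.8, 3) * extent
        r = rng.uniform(1.5, 0.25 * extent.min())
        v |= ball_mask(geom, c, r).voxels
    return BinaryMask(geom, v)
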