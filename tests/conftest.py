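import numpy as np
import pytest

from mandseg.io import BinaryMask, CTVolume, SurfaceMesh
from mandseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic 48^3 phantom (CT + ground truth)."""
    spec = PhantomSpec(grid_shape=(48, 48, 48))
    return generate_phantom(spec, seed=42)


@pytest.fixture(scope="session")
def phantom_spec_48():
    return PhantomSpec(grid_shape=(48, 48, 48))


@pytest.fixture(scope="session")
def postprocess_round_trip_dice():
    """DSC of erode -> smooth -> marching cubes -> voxelize against the
    eroded mask, on a phantom thick enough for the smoothing scale."""
    from mandseg.metrics import dice_coefficient
    from mandseg.postprocess import (PostprocessConfig, erode,
                                     postprocess_prediction,
                                     structuring_element, voxelize_mesh)

    _, gt = generate_phantom(PhantomSpec(grid_shape=(96, 96, 96)), seed=42)
    config = PostprocessConfig()
    mesh = postprocess_prediction(gt, config)
    eroded = erode(gt, structuring_element(config.erosion_connectivity,
                                           config.erosion_radius))
    inside = voxelize_mesh(mesh, gt.shape, gt.spacing, gt.origin)
    return dice_coefficient(inside, eroded.voxels)


def random_mask(rng, shape=(8, 8, 8), p=0.3) -> BinaryMask:
    return BinaryMask(rng.random(shape) < p)


def random_volume(rng, shape=(8, 8, 8)) -> CTVolume:
    return CTVolume(rng.uniform(-1024, 3071, size=shape))


def unit_square_mesh(z=0.0, offset=(0.0, 0.0)) -> SurfaceMesh:
    """Two triangles covering the unit square at constant height z.

    The square extends over [0,1]^2 in the (row, column) axes; ``z`` sets
    the depth coordinate; ``offset`` shifts in-plane.
    """
    oy, ox = offset
    verts = np.array([
        [z, 0 + oy, 0 + ox], [z, 1 + oy, 0 + ox],
        [z, 1 + oy, 1 + ox], [z, 0 + oy, 1 + ox],
    ])
    faces = np.array([[0, 1, 2], [0, 2, 3]])
    return SurfaceMesh(verts, faces)
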