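"""Voxel prediction -> clean surface mesh.

The chain is: binary erosion (removes isolated outlier voxels and
compensates the one-voxel dilation that surface-to-voxel conversion of
the training labels introduces), Gaussian smoothing of the eroded 0/1
field, and marching-cubes extraction of the 0.5 iso-surface.  The mesh,
in world (mm) coordinates, is the product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .io import BinaryMask, SurfaceMesh

__all__ = [
    "PostprocessConfig",
    "NoSurfaceError",
    "erode",
    "smooth_mask",
    "extract_surface",
    "postprocess_prediction",
]


class NoSurfaceError(ValueError):
    """The scalar field does not straddle the iso-level."""


@dataclass
class PostprocessConfig:
    """erosion_radius 0 disables erosion; connectivity 1 is the
    face-adjacent (6-connected) cross element, 3 the full cube."""

    erosion_radius: int = 1
    erosion_connectivity: int = 1
    smoothing_sigma: float = 1.0  # voxels
    iso_level: float = 0.5

    def __post_init__(self):
        if self.smoothing_sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0.0 < self.iso_level < 1.0:
            raise ValueError("iso_level must be in (0, 1)")


def structuring_element(connectivity: int = 1, radius: int = 1) -> np.ndarray:
    """Binary structuring element: iterated generate_binary_structure."""
    if radius < 1:
        return np.ones((1, 1, 1), dtype=bool)
    base = ndimage.generate_binary_structure(3, connectivity)
    return ndimage.iterate_structure(base, radius)


def erode(mask: BinaryMask, element: np.ndarray | None = None) -> BinaryMask:
    """Standard binary erosion (voxels outside the grid count as background)."""
    if element is None:
        element = structuring_element()
    out = ndimage.binary_erosion(mask.voxels, structure=element, border_value=0)
    return BinaryMask(out, spacing=mask.spacing, origin=mask.origin)


def smooth_mask(mask: BinaryMask, sigma: float) -> np.ndarray:
    """Gaussian filter of the 0/1 field (reflective borders); sigma 0 is identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    field = mask.voxels.astype(np.float64)
    if sigma == 0:
        return field
    return ndimage.gaussian_filter(field, sigma, mode="reflect")


def extract_surface(float_volume: np.ndarray, iso_level: float,
                    spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> SurfaceMesh:
    """Marching-cubes iso-surface with vertices in world mm coordinates."""
    vol = np.asarray(float_volume, dtype=np.float64)
    if not (vol.min() < iso_level < vol.max()):
        raise NoSurfaceError(
            f"no surface at iso-level {iso_level}: field range "
            f"[{vol.min():.3g}, {vol.max():.3g}]")
    verts, faces, _, _ = measure.marching_cubes(vol, level=iso_level,
                                                spacing=tuple(float(s) for s in spacing))
    verts = verts + np.asarray(origin, dtype=np.float64)
    # flip winding so face normals point outward (positive enclosed volume)
    return SurfaceMesh(verts, faces[:, ::-1])


def voxelize_mesh(mesh: SurfaceMesh, shape, spacing=(1.0, 1.0, 1.0),
                  origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Fill a closed mesh back onto a voxel grid (even-odd rule).

    For every (row, column) grid line a ray is cast along axis 0 and
    voxel centers are labelled inside when an odd number of triangle
    crossings lies below them.  Inverse of :func:`extract_surface` up to
    discretization.
    """
    shape = tuple(int(s) for s in shape)
    spacing = np.asarray(spacing, dtype=np.float64)
    origin = np.asarray(origin, dtype=np.float64)
    tri = mesh.triangles()
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    # project onto the (row, col) plane; rays travel along axis 0.  Rays
    # are nudged off the voxel-center lattice: marching-cubes vertices lie
    # exactly on it, and rays through edges/vertices miscount crossings.
    eps1, eps2 = 0.0137 * spacing[1], 0.0173 * spacing[2]
    rows = (np.arange(shape[1]) * spacing[1] + origin[1]) + eps1
    cols = (np.arange(shape[2]) * spacing[2] + origin[2]) + eps2
    ry, rx = np.meshgrid(rows, cols, indexing="ij")
    rays = np.stack([ry.ravel(), rx.ravel()], axis=1)  # (R, 2)
    out = np.zeros(shape, dtype=bool)
    zs = np.arange(shape[0]) * spacing[0] + origin[0]
    a2, b2, c2 = a[:, 1:], b[:, 1:], c[:, 1:]
    chunk = 512
    for s in range(0, len(rays), chunk):
        p = rays[s:s + chunk]  # (n, 2)
        # 2D barycentric test of each ray against each triangle's projection
        v0 = c2 - a2
        v1 = b2 - a2
        v2 = p[:, None, :] - a2[None, :, :]
        d00 = np.einsum("ij,ij->i", v0, v0)
        d01 = np.einsum("ij,ij->i", v0, v1)
        d11 = np.einsum("ij,ij->i", v1, v1)
        d20 = np.einsum("nmj,mj->nm", v2, v0)
        d21 = np.einsum("nmj,mj->nm", v2, v1)
        denom = d00 * d11 - d01 * d01
        with np.errstate(divide="ignore", invalid="ignore"):
            u = (d11 * d20 - d01 * d21) / denom
            v = (d00 * d21 - d01 * d20) / denom
        hit = (denom != 0) & (u >= 0) & (v >= 0) & (u + v <= 1)
        # crossing height along axis 0 via barycentric interpolation
        z_hit = (a[None, :, 0] + u * (c[None, :, 0] - a[None, :, 0])
                 + v * (b[None, :, 0] - a[None, :, 0]))
        for n in range(len(p)):
            crossings = np.sort(z_hit[n][hit[n]])
            if crossings.size == 0:
                continue
            inside = (np.searchsorted(crossings, zs) % 2) == 1
            r_idx = (s + n) // shape[2]
            c_idx = (s + n) % shape[2]
            out[:, r_idx, c_idx] = inside
    return out


def postprocess_prediction(mask: BinaryMask,
                           config: PostprocessConfig | None = None) -> SurfaceMesh:
    """Erode -> smooth -> marching cubes.  Raises if erosion empties the mask."""
    config = config or PostprocessConfig()
    m = mask
    if config.erosion_radius > 0:
        m = erode(m, structuring_element(config.erosion_connectivity,
                                         config.erosion_radius))
    if not m.voxels.any():
        raise NoSurfaceError("no surface: mask empty after erosion")
    field = smooth_mask(m, config.smoothing_sigma)
    return extract_surface(field, config.iso_level, spacing=m.spacing, origin=m.origin)
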