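"""HU normalization, spline resampling, bounding boxes and cropping.

The two cascade steps consume fixed-size network inputs; this module maps
between the native CT grid and that input grid.  Resampling is
cell-centered: new voxel centers are placed at ``(i + 0.5) * old/new - 0.5``
in old index coordinates, so the physical extent of the grid is preserved
and spacing rescales by the shape ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import BinaryMask, CTVolume

__all__ = [
    "NormalizedVolume",
    "BoundingBox3D",
    "PreprocessConfig",
    "EmptySegmentationError",
    "clip_and_normalize_hu",
    "resample_volume",
    "resample_mask",
    "compute_bounding_box",
    "pad_bounding_box",
    "crop_to_bbox",
    "embed_prediction",
    "threshold_segment",
]


class EmptySegmentationError(ValueError):
    """A mask that must contain foreground is empty."""


# A normalized volume is a CTVolume whose voxels live in [0, 1]; the alias
# documents intent at call sites.
NormalizedVolume = CTVolume


@dataclass(frozen=True)
class BoundingBox3D:
    """Axis-aligned half-open voxel-index box: ``lower`` incl., ``upper`` excl."""

    lower: tuple[int, int, int]
    upper: tuple[int, int, int]

    def __post_init__(self):
        object.__setattr__(self, "lower", tuple(int(v) for v in self.lower))
        object.__setattr__(self, "upper", tuple(int(v) for v in self.upper))
        if any(u <= l for l, u in zip(self.lower, self.upper)):
            raise ValueError(f"degenerate bounding box {self.lower}..{self.upper}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(u - l for l, u in zip(self.lower, self.upper))  # type: ignore

    @property
    def volume(self) -> int:
        return int(np.prod(self.shape))

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, u) for l, u in zip(self.lower, self.upper))  # type: ignore

    def within(self, grid_shape) -> bool:
        return all(l >= 0 and u <= n for l, u, n in zip(self.lower, self.upper, grid_shape))


@dataclass
class PreprocessConfig:
    """Preprocessing parameters.

    hu_min/hu_max : HU clipping window mapped linearly onto [0, 1]
    target_shape : network input grid (the clinical-scale default is 144^3;
        desk-scale runs use 48^3)
    interpolation_order : spline order for image resampling
    bbox_margin : padding (voxels per axis, at the grid being cropped)
        applied to ground-truth / step-1 bounding boxes
    threshold_hu : HU threshold of the simple baseline segmenter
    """

    hu_min: float = -1024.0
    hu_max: float = 3071.0
    target_shape: tuple[int, int, int] = (144, 144, 144)
    interpolation_order: int = 3
    bbox_margin: int = 8
    threshold_hu: float = 250.0
    binarize_threshold: float = 0.5

    def __post_init__(self):
        self.target_shape = tuple(int(s) for s in self.target_shape)
        if self.hu_min >= self.hu_max:
            raise ValueError("hu_min must be < hu_max")
        if any(s < 8 for s in self.target_shape):
            raise ValueError("target_shape entries must be >= 8")
        if self.bbox_margin < 0:
            raise ValueError("bbox_margin must be >= 0")


def clip_and_normalize_hu(volume: CTVolume, config: PreprocessConfig | None = None) -> NormalizedVolume:
    """Clip HU to [hu_min, hu_max] and map linearly onto [0, 1].

    With the defaults this is ``(clip(hu, -1024, 3071) + 1024) / 4095``.
    """
    config = config or PreprocessConfig()
    hu = np.asarray(volume.voxels, dtype=np.float64)
    if not np.all(np.isfinite(hu)):
        raise ValueError("invalid HU data: non-finite voxels")
    out = (np.clip(hu, config.hu_min, config.hu_max) - config.hu_min) / (config.hu_max - config.hu_min)
    return CTVolume(out, spacing=volume.spacing, origin=volume.origin)


def _resample_array(data: np.ndarray, target_shape, order: int) -> np.ndarray:
    """Cell-centered resample of a 3D array to target_shape."""
    target_shape = tuple(int(s) for s in target_shape)
    if any(s < 1 for s in target_shape):
        raise ValueError("target shape entries must be >= 1")
    if tuple(data.shape) == target_shape:
        return data.astype(np.float64, copy=True)
    axes_coords = [
        (np.arange(n_new) + 0.5) * (n_old / n_new) - 0.5
        for n_old, n_new in zip(data.shape, target_shape)
    ]
    grid = np.meshgrid(*axes_coords, indexing="ij")
    coords = np.stack(grid, axis=0)
    return ndimage.map_coordinates(
        data.astype(np.float64), coords, order=order, mode="nearest"
    )


def _resampled_geometry(volume, target_shape):
    ratios = [n_old / n_new for n_old, n_new in zip(volume.shape, target_shape)]
    spacing = tuple(s * r for s, r in zip(volume.spacing, ratios))
    # new center 0 sits at old index 0.5*r - 0.5
    origin = tuple(
        o + (0.5 * r - 0.5) * s for o, s, r in zip(volume.origin, volume.spacing, ratios)
    )
    return spacing, origin


def resample_volume(volume: CTVolume, target_shape, order: int = 3) -> CTVolume:
    """Spline-resample a volume to ``target_shape``, preserving physical extent."""
    if not 0 <= order <= 5:
        raise ValueError("spline order must be in 0..5")
    out = _resample_array(np.asarray(volume.voxels), target_shape, order)
    spacing, origin = _resampled_geometry(volume, target_shape)
    return CTVolume(out, spacing=spacing, origin=origin)


def resample_mask(mask: BinaryMask, target_shape) -> BinaryMask:
    """Resample a label grid: linear interpolation of the 0/1 field, then >= 0.5.

    Linear rather than cubic interpolation avoids spline overshoot creating
    spurious labels.
    """
    out = _resample_array(mask.voxels.astype(np.float64), target_shape, order=1)
    spacing, origin = _resampled_geometry(mask, target_shape)
    return BinaryMask(out >= 0.5, spacing=spacing, origin=origin)


def compute_bounding_box(mask: BinaryMask | np.ndarray) -> BoundingBox3D:
    """Tightest half-open box containing all true voxels."""
    vox = mask.voxels if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    idx = np.nonzero(vox)
    if idx[0].size == 0:
        raise EmptySegmentationError("empty segmentation: no foreground voxels")
    lower = tuple(int(ax.min()) for ax in idx)
    upper = tuple(int(ax.max()) + 1 for ax in idx)
    return BoundingBox3D(lower, upper)


def pad_bounding_box(bbox: BoundingBox3D, margin, grid_shape) -> BoundingBox3D:
    """Expand a box by ``margin`` voxels per axis, clamped to the grid."""
    if np.isscalar(margin):
        margin = (margin,) * 3
    lower = tuple(max(0, l - int(m)) for l, m in zip(bbox.lower, margin))
    upper = tuple(min(int(n), u + int(m)) for u, m, n in zip(bbox.upper, margin, grid_shape))
    return BoundingBox3D(lower, upper)


def crop_to_bbox(volume_or_mask, bbox: BoundingBox3D):
    """Sub-grid copy; the origin shifts by ``lower * spacing``."""
    v = volume_or_mask
    if not bbox.within(v.shape):
        raise ValueError(f"bounding box {bbox} exceeds grid {v.shape}")
    sub = v.voxels[bbox.slices()].copy()
    origin = tuple(o + l * s for o, l, s in zip(v.origin, bbox.lower, v.spacing))
    cls = BinaryMask if isinstance(v, BinaryMask) else CTVolume
    return cls(sub, spacing=v.spacing, origin=origin)


def embed_prediction(cropped_mask: BinaryMask, bbox: BoundingBox3D, full_shape,
                     spacing=None, origin=None) -> BinaryMask:
    """Place a cropped mask back into a full-size grid (false outside the box)."""
    if tuple(cropped_mask.shape) != tuple(bbox.shape):
        raise ValueError(
            f"cropped mask shape {cropped_mask.shape} != bbox extent {bbox.shape}"
        )
    full = np.zeros(tuple(int(s) for s in full_shape), dtype=bool)
    full[bbox.slices()] = cropped_mask.voxels
    spacing = spacing if spacing is not None else cropped_mask.spacing
    if origin is None:
        origin = tuple(
            o - l * s for o, l, s in zip(cropped_mask.origin, bbox.lower, spacing)
        )
    return BinaryMask(full, spacing=spacing, origin=origin)


def threshold_segment(volume: CTVolume, threshold_hu: float = 250.0) -> BinaryMask:
    """Baseline segmenter: true where HU >= threshold (inclusive).

    On CT with dental metal this picks up streak artifacts that a trained
    model learns to reject, which is exactly what makes it a useful
    baseline.
    """
    return BinaryMask(np.asarray(volume.voxels) >= threshold_hu,
                      spacing=volume.spacing, origin=volume.origin)
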