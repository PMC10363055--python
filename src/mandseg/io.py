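"""Volume and mesh I/O plus the geometric core types.

All downstream modules consume only :class:`CTVolume`, :class:`BinaryMask`
and :class:`SurfaceMesh`; nothing else in the package touches files.

Axis convention: voxel arrays are ``(depth, row, column)`` with the depth
axis being the slice/axial axis.  Spacing and origin follow the same
order, in mm.  Only axis-aligned geometries are supported; DICOM series
with oblique orientation are rejected.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
import trimesh

__all__ = [
    "CTVolume",
    "BinaryMask",
    "SurfaceMesh",
    "InconsistentSeriesError",
    "AmbiguousSeriesError",
    "MalformedSTLError",
    "read_dicom_series",
    "read_nifti",
    "write_nifti",
    "read_stl",
    "write_stl",
    "mask_to_world",
]


class InconsistentSeriesError(ValueError):
    """DICOM stack has missing, duplicate or irregular slice positions."""


class AmbiguousSeriesError(ValueError):
    """Directory contains more than one DICOM series."""


class MalformedSTLError(ValueError):
    """STL file is truncated or otherwise unreadable."""


def _as_triple(x) -> tuple[float, float, float]:
    t = tuple(float(v) for v in x)
    if len(t) != 3:
        raise ValueError(f"expected 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass
class CTVolume:
    """3D scalar grid of Hounsfield units.

    voxels : float array, axis order (depth, row, column)
    spacing : per-axis voxel size in mm, same order, all > 0
    origin : world coordinates (mm) of the voxel at index (0, 0, 0)
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("CTVolume requires a 3D array")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive on all axes")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("invalid HU data: non-finite voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]


@dataclass
class BinaryMask:
    """Boolean grid geometrically aligned to a :class:`CTVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError("BinaryMask requires a 3D array")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive on all axes")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def same_grid(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class SurfaceMesh:
    """Triangle mesh with vertices in world (mm) coordinates."""

    vertices: np.ndarray
    faces: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), dtype=np.int64))

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """(n_faces, 3, 3) array of triangle corner coordinates."""
        return self.vertices[self.faces]

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)


def mask_to_world(index_triple, spacing, origin) -> np.ndarray:
    """World mm coordinates of a voxel index: ``origin + index * spacing``."""
    idx = np.asarray(index_triple, dtype=np.float64)
    return np.asarray(origin, dtype=np.float64) + idx * np.asarray(spacing, dtype=np.float64)


# ---------------------------------------------------------------------------
# DICOM


def read_dicom_series(directory_path) -> CTVolume:
    """Read a single-series axial DICOM stack into a :class:`CTVolume`.

    Slices are sorted by position along the slice axis regardless of file
    order; stored values are converted to HU with the rescale slope and
    intercept carried by the files.  Raises
    :class:`AmbiguousSeriesError` for multi-series directories and
    :class:`InconsistentSeriesError` for duplicate or irregularly spaced
    slice positions.
    """
    directory = Path(directory_path)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            datasets.append(pydicom.dcmread(str(p)))
        except pydicom.errors.InvalidDicomError:
            continue
    if not datasets:
        raise InconsistentSeriesError(f"no DICOM files in {directory}")
    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) > 1:
        raise AmbiguousSeriesError(f"ambiguous series: {len(uids)} series in {directory}")

    def slice_pos(ds) -> float:
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(ds.SliceLocation)

    datasets.sort(key=slice_pos)
    positions = np.array([slice_pos(ds) for ds in datasets])
    if len(datasets) > 1:
        diffs = np.diff(positions)
        if np.any(diffs <= 0):
            raise InconsistentSeriesError("inconsistent series: duplicate slice positions")
        if not np.allclose(diffs, diffs[0], atol=1e-3):
            raise InconsistentSeriesError("inconsistent series: irregular slice spacing")
        slice_spacing = float(diffs[0])
    else:
        slice_spacing = float(getattr(datasets[0], "SliceThickness", 1.0))

    first = datasets[0]
    orient = getattr(first, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0])
    if not np.allclose(np.abs(orient), [1, 0, 0, 0, 1, 0], atol=1e-3):
        raise InconsistentSeriesError("inconsistent series: non-axis-aligned orientation")
    row_sp, col_sp = (float(v) for v in first.PixelSpacing)

    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float64) * slope + intercept)
    voxels = np.stack(slices, axis=0)
    pos0 = first.ImagePositionPatient if hasattr(first, "ImagePositionPatient") else (0, 0, 0)
    origin = (float(positions[0]), float(pos0[1]), float(pos0[0]))
    return CTVolume(voxels, spacing=(slice_spacing, row_sp, col_sp), origin=origin)


# ---------------------------------------------------------------------------
# NIfTI
#
# On-disk layout: the array is stored exactly as held in memory
# (depth, row, column) with an axis-aligned affine diag(spacing) + origin,
# so write -> read round trips are lossless by construction.


def write_nifti(volume_or_mask, path) -> None:
    """Write a volume or mask as NIfTI-1 with lossless geometry."""
    v = volume_or_mask
    if isinstance(v, BinaryMask):
        data = v.voxels.astype(np.uint8)
    else:
        data = np.asarray(v.voxels, dtype=np.float32)
    affine = np.diag(list(v.spacing) + [1.0]).astype(np.float64)
    affine[:3, 3] = v.origin
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))


def read_nifti(path, kind: str = "image"):
    """Read a NIfTI-1 volume.

    kind='image' returns a :class:`CTVolume`; kind='mask' binarizes
    (any nonzero voxel -> True) and returns a :class:`BinaryMask`.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"unsupported dimensionality: {data.ndim}D NIfTI")
    affine = img.affine
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in affine[:3, 3])
    if kind == "mask":
        return BinaryMask(data != 0, spacing=spacing, origin=origin)
    if kind == "image":
        return CTVolume(np.asarray(data, dtype=np.float64), spacing=spacing, origin=origin)
    raise ValueError(f"unknown kind {kind!r}")


# ---------------------------------------------------------------------------
# STL


def write_stl(mesh: SurfaceMesh, path, mode: str = "binary") -> None:
    """Write a mesh as STL (binary: 80-byte header, uint32 count, 50 B/facet)."""
    if mode not in ("binary", "ascii"):
        raise ValueError(f"mode must be 'binary' or 'ascii', got {mode!r}")
    path = Path(path)
    if mesh.n_faces == 0:
        # trimesh refuses empty meshes; emit the trivial well-formed file.
        if mode == "binary":
            path.write_bytes(b"\0" * 80 + struct.pack("<I", 0))
        else:
            path.write_text("solid mandseg\nendsolid mandseg\n")
        return
    tm = mesh.to_trimesh()
    file_type = "stl" if mode == "binary" else "stl_ascii"
    tm.export(str(path), file_type=file_type)


def read_stl(path) -> SurfaceMesh:
    """Read an STL file, welding vertices by exact coordinate equality."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) >= 84 and not raw.lstrip()[:5] == b"solid":
        n_tri = struct.unpack("<I", raw[80:84])[0]
        if n_tri == 0:
            return SurfaceMesh(np.zeros((0, 3)))
        if len(raw) < 84 + 50 * n_tri:
            raise MalformedSTLError(f"malformed STL: {path} truncated")
    try:
        tm = trimesh.load(str(path), file_type="stl", process=False)
    except Exception as exc:  # pragma: no cover - trimesh error breadth
        raise MalformedSTLError(f"malformed STL: {path}: {exc}") from exc
    if isinstance(tm, trimesh.Scene):
        if not tm.geometry:
            return SurfaceMesh(np.zeros((0, 3)))
        tm = next(iter(tm.geometry.values()))
    verts = np.asarray(tm.vertices, dtype=np.float64)
    faces = np.asarray(tm.faces, dtype=np.int64)
    if len(faces) == 0:
        return SurfaceMesh(np.zeros((0, 3)))
    # exact-bit-equality weld
    flat = verts[faces.reshape(-1)]
    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
    return SurfaceMesh(uniq, inverse.reshape(-1, 3))
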