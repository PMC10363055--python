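"""Deterministic synthetic mandible phantoms.

The generator emulates the statistical structure of head-and-neck CT
around the lower jaw: a horseshoe-shaped bony arch (half torus in the
axial plane) joined to two vertical rami, each capped by two thin prongs
standing in for the condylar and coronoid processes; optional
hemispherical tooth bumps along the cranial rim of the arch (tooth count
0 gives an edentulous phantom).  Hounsfield units are painted per tissue
class (air approx. -1000 HU, a soft-tissue envelope around the bone
approx. +40 HU, bone approx. +1200 HU) with additive Gaussian noise, and
dental metal can be simulated as small seeds above 2500 HU that cast
bright and dark streaks through the axial plane -- the classic ray-shaped
reconstruction artifact.  Streaks corrupt only the CT image, never the
ground-truth label, mirroring ground truths from which artifacts were
manually removed.

Everything is driven by an explicit seed and is bit-reproducible;
per-sample sub-seeds are derived with ``numpy.random.SeedSequence`` so a
dataset manifest fully determines its contents.

Axis convention: axis 0 is cranio-caudal (index 0 = cranial), axes 1 and
2 are the lateral/axial-plane axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io import BinaryMask, CTVolume

__all__ = ["PhantomSpec", "generate_phantom", "add_metal_artifacts", "generate_dataset"]


@dataclass
class PhantomSpec:
    """Parameter ranges for phantom sampling (ranges are [low, high])."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    lateral_spacing_mm: tuple[float, float] = (0.2, 0.9)
    axial_spacing_mm: tuple[float, float] = (0.5, 1.5)
    # geometry, as fractions of the smaller lateral grid extent; the jaw
    # occupies only part of the field of view, as in head-and-neck CT,
    # which is what makes the coarse-to-fine crop worthwhile
    arch_radius_frac: tuple[float, float] = (0.17, 0.23)
    arch_thickness_frac: tuple[float, float] = (0.055, 0.075)
    ramus_height_frac: tuple[float, float] = (0.3, 0.42)
    tooth_count: tuple[int, int] = (0, 8)
    tooth_radius_frac: tuple[float, float] = (0.03, 0.05)
    # HU model
    air_hu: float = -1000.0
    soft_tissue_hu: float = 40.0
    bone_hu: float = 1200.0
    noise_sd_hu: float = 40.0
    partial_volume_sigma: float = 0.8  # voxels; CT point-spread proxy
    # metal / streaks
    metal_hu: float = 3000.0
    n_metal_seeds: tuple[int, int] = (1, 3)
    streaks_per_seed: tuple[int, int] = (6, 12)
    streak_bright_hu: float = 1800.0
    streak_dark_hu: float = -900.0
    streak_decay_frac: float = 0.5  # e-folding length as fraction of grid

    def __post_init__(self):
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if not self.bone_hu > self.soft_tissue_hu > self.air_hu:
            raise ValueError("HU ordering must be bone > soft tissue > air")
        for name in ("lateral_spacing_mm", "axial_spacing_mm", "arch_radius_frac",
                     "arch_thickness_frac", "ramus_height_frac", "tooth_count",
                     "tooth_radius_frac", "n_metal_seeds", "streaks_per_seed"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"range {name} must be ordered low <= high")


class InfeasibleSpecError(ValueError):
    """Grid too small to contain a resolvable arch."""


def _draw(rng, lohi):
    return rng.uniform(lohi[0], lohi[1])


def _build_label(spec: PhantomSpec, rng) -> tuple[np.ndarray, dict]:
    """Voxelize the mandible proxy; returns (mask, geometry record)."""
    dz, dy, dx = spec.grid_shape
    lat = min(dy, dx)
    if lat < 24 or dz < 24:
        raise InfeasibleSpecError(f"spec infeasible: grid {spec.grid_shape} too small")
    radius = _draw(rng, spec.arch_radius_frac) * lat
    thick = max(1.6, _draw(rng, spec.arch_thickness_frac) * lat)
    ramus_h = _draw(rng, spec.ramus_height_frac) * dz
    n_teeth = int(rng.integers(spec.tooth_count[0], spec.tooth_count[1] + 1))
    tooth_r = max(1.2, _draw(rng, spec.tooth_radius_frac) * lat)

    cy = dy * rng.uniform(0.46, 0.54)
    cx = dx * rng.uniform(0.46, 0.54)
    z_body = dz * rng.uniform(0.62, 0.72)  # caudal body height
    half_span = np.deg2rad(rng.uniform(95.0, 110.0))  # arch opens posteriorly

    zz, yy, xx = np.meshgrid(np.arange(dz), np.arange(dy), np.arange(dx),
                             indexing="ij", sparse=True)
    # polar coordinates in the axial plane; arch apex at angle 0 (+row axis)
    ang = np.arctan2(xx - cx, yy - cy)
    rho = np.hypot(yy - cy, xx - cx)
    in_span = np.abs(ang) <= half_span
    torus = (np.square(rho - radius) + np.square(zz - z_body)) <= thick ** 2
    label = torus & in_span

    # rami: vertical cylinders at the arch ends, rising cranially
    ends = []
    for sgn in (+1.0, -1.0):
        a = sgn * half_span
        ey, ex = cy + radius * np.cos(a), cx + radius * np.sin(a)
        ends.append((ey, ex))
        cyl = (np.hypot(yy - ey, xx - ex) <= thick) & (zz <= z_body) & (
            zz >= z_body - ramus_h)
        label = label | cyl
        # two thin prongs per ramus: condylar / coronoid proxies
        for off in (-1.1, 1.1):
            py, px = ey + off * thick * np.cos(a + np.pi / 2), ex + off * thick * np.sin(a + np.pi / 2)
            prong = (np.hypot(yy - py, xx - px) <= max(1.1, 0.45 * thick)) & (
                zz <= z_body - ramus_h + 1) & (zz >= z_body - ramus_h - 0.35 * ramus_h)
            label = label | prong

    # teeth: hemispherical bumps on the cranial rim of the arch
    teeth = []
    if n_teeth > 0:
        angles = np.linspace(-0.7 * half_span, 0.7 * half_span, n_teeth)
        for a in angles:
            ty, tx = cy + radius * np.cos(a), cx + radius * np.sin(a)
            tz = z_body - thick
            teeth.append((float(tz), float(ty), float(tx)))
            bump = (np.square(zz - tz) + np.square(yy - ty) + np.square(xx - tx)
                    <= tooth_r ** 2) & (zz <= tz)
            label = label | bump

    geo = {
        "radius": float(radius), "thickness": float(thick), "ramus_height": float(ramus_h),
        "center": (float(cy), float(cx)), "z_body": float(z_body),
        "half_span_deg": float(np.rad2deg(half_span)), "n_teeth": n_teeth,
        "teeth": teeth, "ramus_ends": [(float(a), float(b)) for a, b in ends],
    }
    return label, geo


def generate_phantom(spec: PhantomSpec, seed) -> tuple[CTVolume, BinaryMask]:
    """Generate one phantom CT + ground-truth mask, bit-reproducible per seed."""
    rng = np.random.default_rng(seed)
    label, _ = _build_label(spec, rng)
    ct = _paint_hu(label, spec, rng)
    sp_lat = _draw(rng, spec.lateral_spacing_mm)
    sp_ax = _draw(rng, spec.axial_spacing_mm)
    spacing = (sp_ax, sp_lat, sp_lat)
    return (CTVolume(ct, spacing=spacing), BinaryMask(label, spacing=spacing))


def _paint_hu(label: np.ndarray, spec: PhantomSpec, rng) -> np.ndarray:
    envelope = ndimage.binary_dilation(label, iterations=3)
    ct = np.full(label.shape, spec.air_hu, dtype=np.float64)
    ct[envelope] = spec.soft_tissue_hu
    ct[label] = spec.bone_hu
    if spec.partial_volume_sigma > 0:
        # blur before noise: mimics the scanner point-spread function, so
        # bone boundaries show partial-volume values instead of a hard step
        ct = ndimage.gaussian_filter(ct, spec.partial_volume_sigma, mode="nearest")
    ct += rng.normal(0.0, spec.noise_sd_hu, size=label.shape)
    return ct


def add_metal_artifacts(ct: CTVolume, mask: BinaryMask, spec: PhantomSpec, seed) -> CTVolume:
    """Add metal seeds (> 2500 HU) and axial-plane streaks to the CT only.

    Streaks alternate bright (>= +several hundred HU over tissue) and dark,
    decaying with distance from the seed; the ground truth is untouched.
    """
    rng = np.random.default_rng(seed)
    vox = np.asarray(ct.voxels).copy()
    dz, dy, dx = vox.shape
    n_seeds = int(rng.integers(spec.n_metal_seeds[0], spec.n_metal_seeds[1] + 1))
    if n_seeds == 0:
        return CTVolume(vox, spacing=ct.spacing, origin=ct.origin)

    # seeds sit on the cranial surface of the label (tooth territory):
    # label voxels whose cranial neighbour is background
    lab = mask.voxels
    cranial_surface = lab & ~np.roll(lab, 1, axis=0)
    cranial_surface[0] = False
    cand = np.argwhere(cranial_surface)
    if len(cand) == 0:
        cand = np.argwhere(lab)
    decay_len = spec.streak_decay_frac * max(dy, dx)
    for s in range(n_seeds):
        z0, y0, x0 = cand[rng.integers(len(cand))]
        zlo, zhi = max(0, z0 - 1), min(dz, z0 + 2)
        ylo, yhi = max(0, y0 - 1), min(dy, y0 + 2)
        xlo, xhi = max(0, x0 - 1), min(dx, x0 + 2)
        vox[zlo:zhi, ylo:yhi, xlo:xhi] = spec.metal_hu
        n_rays = int(rng.integers(spec.streaks_per_seed[0], spec.streaks_per_seed[1] + 1))
        for r in range(n_rays):
            theta = rng.uniform(0.0, 2.0 * np.pi)
            bright = (r % 2 == 0)
            amp = spec.streak_bright_hu if bright else spec.streak_dark_hu
            t = np.arange(1.0, max(dy, dx) * 1.5)
            ys = np.rint(y0 + t * np.cos(theta)).astype(int)
            xs = np.rint(x0 + t * np.sin(theta)).astype(int)
            keep = (ys >= 0) & (ys < dy) & (xs >= 0) & (xs < dx)
            # floor at 0.35 keeps bright streaks well above the 250 HU
            # bone threshold along their whole visible length
            fade = np.maximum(np.exp(-t[keep] / decay_len), 0.35)
            vox[z0, ys[keep], xs[keep]] += amp * fade
    return CTVolume(vox, spacing=ct.spacing, origin=ct.origin)


@dataclass
class DatasetManifest:
    master_seed: int
    records: list = field(default_factory=list)  # per-sample dicts


def generate_dataset(n: int, spec: PhantomSpec, seed: int,
                     artifact_fraction: float = 0.5,
                     edentulous_fraction: float = 0.2):
    """Generate ``n`` phantoms with derived sub-seeds and a reproducible manifest.

    A Bernoulli(artifact_fraction) coin decides metal streaks per sample;
    Bernoulli(edentulous_fraction) forces tooth count 0.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    master = np.random.SeedSequence(seed)
    coin = np.random.default_rng(master.spawn(1)[0])
    samples, manifest = [], DatasetManifest(master_seed=int(seed))
    for i in range(n):
        sub = int(np.random.SeedSequence([int(seed), i]).generate_state(1)[0])
        artifacts = bool(coin.random() < artifact_fraction)
        edentulous = bool(coin.random() < edentulous_fraction)
        s = replace(spec, tooth_count=(0, 0)) if edentulous else spec
        ct, mask = generate_phantom(s, sub)
        if artifacts:
            ct = add_metal_artifacts(ct, mask, s, sub + 1)
        samples.append((ct, mask))
        manifest.records.append({
            "index": i, "seed": sub, "artifacts": artifacts,
            "edentulous": edentulous, "spacing": list(ct.spacing),
        })
    return samples, manifest
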