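"""Stochastic training-time augmentation for paired image/label samples.

Eight transform families are supported: mirroring, spatial translation,
Gaussian blurring, additive Gaussian noise, transient down-sampling
(down- then up-sampling, simulating lower acquisition resolution),
scaling, rotation and elastic deformation.  Spatial transforms are
applied identically to image and label (image with linear interpolation,
label with linear interpolation followed by a 0.5 threshold); intensity
transforms touch the image only.  Voxels transported from outside the
field of view are filled with 0, i.e. normalized air.

Randomness is split from geometry: :func:`sample_transform_plan` draws
which transforms fire and with which concrete parameters, producing a
serializable plan; :func:`apply_transform_plan` executes a plan
deterministically.  ``augment_sample`` is the composition.  Transforms
are applied in the fixed order listed above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "AugmentConfig",
    "TransformSpec",
    "sample_transform_plan",
    "apply_transform_plan",
    "augment_sample",
    "TRANSFORM_ORDER",
]

TRANSFORM_ORDER = (
    "mirror", "translate", "blur", "noise", "downsample", "scale", "rotate", "elastic",
)


@dataclass
class TransformSpec:
    enabled: bool = True
    prob: float = 0.5
    # range semantics depend on the transform; see AugmentConfig fields

    def __post_init__(self):
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError("probability must be in [0, 1]")


@dataclass
class AugmentConfig:
    """Per-transform enable flags, firing probabilities and parameter ranges.

    Defaults follow common practice for head CT patches: lateral mirroring
    at p = 0.5 per axis, translations up to +-10 voxels, blur sigma in
    [0.5, 1.5] voxels, additive noise sigma up to 0.05 in normalized
    intensity, transient down-sampling by a factor up to 2, scaling in
    [0.85, 1.15], rotations up to +-15 degrees per axis, and elastic
    deformations from a 32-voxel control grid with displacement sigma up
    to 6 voxels.
    """

    mirror: TransformSpec = field(default_factory=lambda: TransformSpec(prob=0.5))
    mirror_axes: tuple[int, ...] = (1, 2)  # lateral axes only
    translate: TransformSpec = field(default_factory=lambda: TransformSpec(prob=0.2))
    translate_range: tuple[float, float] = (-10.0, 10.0)
    blur: TransformSpec = field(default_factory=lambda: TransformSpec(prob=0.2))
    blur_sigma_range: tuple[float, float] = (0.5, 1.5)
    noise: TransformSpec = field(default_factory=lambda: TransformSpec(prob=0.15))
    noise_sigma_range: tuple[float, float] = (0.0, 0.05)
    downsample: TransformSpec = field(default_factory=lambda: TransformSpec(prob=0.15))
    downsample_range: tuple[float, float] = (1.0, 2.0)
    scale: TransformSpec = field(default_factory=lambda: TransformSpec(prob=0.2))
    scale_range: tuple[float, float] = (0.85, 1.15)
    rotate: TransformSpec = field(default_factory=lambda: TransformSpec(prob=0.2))
    rotate_deg_range: tuple[float, float] = (-15.0, 15.0)
    elastic: TransformSpec = field(default_factory=lambda: TransformSpec(prob=0.1))
    elastic_spacing: float = 32.0
    elastic_sigma_range: tuple[float, float] = (0.0, 6.0)

    @classmethod
    def disabled(cls) -> "AugmentConfig":
        cfg = cls()
        for name in TRANSFORM_ORDER:
            getattr(cfg, name).enabled = False
        return cfg


def sample_transform_plan(config: AugmentConfig, rng) -> list[dict]:
    """Draw a concrete, replayable plan: a list of {'name': ..., params} dicts."""
    rng = np.random.default_rng(rng)
    plan: list[dict] = []
    for name in TRANSFORM_ORDER:
        spec: TransformSpec = getattr(config, name)
        if name == "mirror":
            if not spec.enabled:
                continue
            axes = [int(a) for a in config.mirror_axes if rng.random() < spec.prob]
            if axes:
                plan.append({"name": "mirror", "axes": axes})
            continue
        if not spec.enabled or rng.random() >= spec.prob:
            continue
        if name == "translate":
            shift = [float(rng.uniform(*config.translate_range)) for _ in range(3)]
            plan.append({"name": "translate", "shift": shift})
        elif name == "blur":
            plan.append({"name": "blur", "sigma": float(rng.uniform(*config.blur_sigma_range))})
        elif name == "noise":
            plan.append({"name": "noise", "sigma": float(rng.uniform(*config.noise_sigma_range)),
                         "seed": int(rng.integers(2 ** 31))})
        elif name == "downsample":
            plan.append({"name": "downsample", "factor": float(rng.uniform(*config.downsample_range))})
        elif name == "scale":
            plan.append({"name": "scale", "factor": float(rng.uniform(*config.scale_range))})
        elif name == "rotate":
            plan.append({"name": "rotate",
                         "angles_deg": [float(rng.uniform(*config.rotate_deg_range)) for _ in range(3)]})
        elif name == "elastic":
            plan.append({"name": "elastic", "spacing": float(config.elastic_spacing),
                         "sigma": float(rng.uniform(*config.elastic_sigma_range)),
                         "seed": int(rng.integers(2 ** 31))})
    return plan


SPATIAL = {"mirror", "translate", "scale", "rotate", "elastic"}


def _warp(data, coords, order):
    return ndimage.map_coordinates(data, coords, order=order, mode="constant", cval=0.0)


def _center_coords(shape):
    grid = np.meshgrid(*(np.arange(n, dtype=np.float64) for n in shape), indexing="ij")
    return np.stack(grid), (np.asarray(shape, dtype=np.float64) - 1.0) / 2.0


def _apply_spatial(image, mask, coords):
    img = ndimage.map_coordinates(image, coords, order=1, mode="constant", cval=0.0)
    if mask is None:
        return img, None
    m = ndimage.map_coordinates(mask.astype(np.float64), coords, order=1,
                                mode="constant", cval=0.0)
    return img, m >= 0.5


def _rotation_matrix(angles_deg):
    out = np.eye(3)
    for axis, ang in enumerate(angles_deg):
        a = np.deg2rad(ang)
        c, s = np.cos(a), np.sin(a)
        rot = np.eye(3)
        i, j = [k for k in range(3) if k != axis]
        rot[i, i], rot[i, j], rot[j, i], rot[j, j] = c, -s, s, c
        out = rot @ out
    return out


def apply_transform_plan(image, mask, plan):
    """Execute a plan on an image (float, [0,1]) and optional binary mask."""
    image = np.asarray(image, dtype=np.float64)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != image.shape:
            raise ValueError("mismatched image/mask grids")
    for step in plan:
        name = step["name"]
        if name == "mirror":
            for ax in step["axes"]:
                image = np.flip(image, axis=ax)
                mask = np.flip(mask, axis=ax) if mask is not None else None
        elif name == "translate":
            coords, _ = _center_coords(image.shape)
            shift = np.asarray(step["shift"])[:, None, None, None]
            image, mask = _apply_spatial(image, mask, coords - shift)
        elif name == "scale":
            coords, center = _center_coords(image.shape)
            c = center[:, None, None, None]
            image, mask = _apply_spatial(image, mask, (coords - c) / step["factor"] + c)
        elif name == "rotate":
            coords, center = _center_coords(image.shape)
            c = center[:, None, None, None]
            rot = _rotation_matrix(step["angles_deg"])
            flat = (coords - c).reshape(3, -1)
            new = (rot.T @ flat).reshape(coords.shape) + c
            image, mask = _apply_spatial(image, mask, new)
        elif name == "elastic":
            coords, _ = _center_coords(image.shape)
            rng = np.random.default_rng(step["seed"])
            from .preprocess import _resample_array
            n_ctrl = [max(2, int(np.ceil(n / step["spacing"])) + 1) for n in image.shape]
            disp = [rng.normal(0.0, step["sigma"], size=n_ctrl) for _ in range(3)]
            full = np.stack([_resample_array(d, image.shape, order=3) for d in disp])
            image, mask = _apply_spatial(image, mask, coords + full)
        elif name == "blur":
            image = ndimage.gaussian_filter(image, step["sigma"], mode="nearest")
        elif name == "noise":
            rng = np.random.default_rng(step["seed"])
            image = image + rng.normal(0.0, step["sigma"], size=image.shape)
        elif name == "downsample":
            f = step["factor"]
            if f > 1.0:
                small = [max(1, int(round(n / f))) for n in image.shape]
                from .preprocess import _resample_array
                low = _resample_array(image, small, order=1)
                image = _resample_array(low, image.shape, order=1)
        else:
            raise ValueError(f"unknown transform {name!r}")
    return image, mask


def save_plan(plan: list[dict], path) -> None:
    """Write a transform plan as YAML for replay/debugging."""
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(plan, fh)


def load_plan(path) -> list[dict]:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh) or []


def augment_sample(image, mask, config: AugmentConfig, rng):
    """Draw a plan from ``rng`` and apply it to the pair.

    The same ``rng`` state yields identical output; intensity transforms
    never alter the mask.
    """
    plan = sample_transform_plan(config, rng)
    return apply_transform_plan(image, mask, plan)
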