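"""Two-step coarse-to-fine segmentation cascade.

Step 1 segments the whole volume down-sampled to the network input size
and serves only to localize the mandible: its binarized prediction yields
a bounding box.  Step 2 segments the full-resolution crop of that box,
resampled to the same input size, and its prediction is mapped back and
embedded into the original grid.  During *training*, step 2 uses
ground-truth bounding boxes; during *inference* it uses step-1 boxes --
the ground truth is never read at inference time (the prediction
functions do not accept it).

Both networks share architecture, optimizer and loss settings; only the
training data differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import losses, preprocess, unet
from .augment import AugmentConfig, augment_sample
from .io import BinaryMask, CTVolume
from .losses import LossParams
from .preprocess import BoundingBox3D, EmptySegmentationError, PreprocessConfig
from .unet import UNet3D, UNetConfig

__all__ = [
    "CascadeModel",
    "DatasetSplit",
    "TrainConfig",
    "RegionNotFoundError",
    "split_dataset",
    "make_step1_sample",
    "make_step2_sample",
    "train_step",
    "predict_single_step",
    "predict_two_step",
    "scale_bbox_to_grid",
]


class RegionNotFoundError(RuntimeError):
    """Step-1 prediction contains no foreground; no region of interest."""


@dataclass
class DatasetSplit:
    train: list
    validation: list
    test: list
    seed: int

    def __post_init__(self):
        parts = [set(self.train), set(self.validation), set(self.test)]
        total = sum(len(p) for p in parts)
        if len(set().union(*parts)) != total:
            raise ValueError("split partitions must be disjoint")


def split_dataset(ids, fractions, seed) -> DatasetSplit:
    """Uniformly random disjoint train/validation/test partition.

    Sizes are largest-remainder rounded so they are exhaustive; e.g. 307
    ids at fractions (0.808, 0.098, 0.094) give sizes (248, 30, 29).
    """
    ids = list(ids)
    fractions = [float(f) for f in fractions]
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be three numbers summing to 1")
    n = len(ids)
    raw = [f * n for f in fractions]
    sizes = [int(np.floor(r)) for r in raw]
    remainders = [r - s for r, s in zip(raw, sizes)]
    for _ in range(n - sum(sizes)):
        i = int(np.argmax(remainders))
        sizes[i] += 1
        remainders[i] = -1.0
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [ids[i] for i in order]
    a, b = sizes[0], sizes[0] + sizes[1]
    return DatasetSplit(shuffled[:a], shuffled[a:b], shuffled[b:], seed=int(seed))


def make_step1_sample(ct: CTVolume, gt_mask: BinaryMask | None,
                      config: PreprocessConfig):
    """Whole-volume training sample: normalize + spline-resample to target shape."""
    norm = preprocess.clip_and_normalize_hu(ct, config)
    image = preprocess.resample_volume(norm, config.target_shape,
                                       order=config.interpolation_order)
    image.voxels = np.clip(image.voxels, 0.0, 1.0)  # spline overshoot guard
    if gt_mask is None:
        return image, None
    label = preprocess.resample_mask(gt_mask, config.target_shape)
    return image, label


def make_step2_sample(ct: CTVolume, gt_mask: BinaryMask,
                      config: PreprocessConfig):
    """Crop to the padded ground-truth box, then normalize + resample both."""
    bbox = preprocess.compute_bounding_box(gt_mask)  # raises on empty gt
    bbox = preprocess.pad_bounding_box(bbox, config.bbox_margin, ct.shape)
    ct_crop = preprocess.crop_to_bbox(ct, bbox)
    gt_crop = preprocess.crop_to_bbox(gt_mask, bbox)
    return make_step1_sample(ct_crop, gt_crop, config)


@dataclass
class TrainConfig:
    """Optimization settings shared by both cascade steps.

    The clinical-scale default step size is 1e-4; desk-scale runs on
    phantoms converge fastest around 3e-3.
    """

    steps: int = 200
    batch_size: int = 2
    learning_rate: float = 1e-4
    # step-decay schedule: multiply the rate by lr_decay_factor after
    # lr_decay_step optimizer steps (1.0 disables)
    lr_decay_step: int = 0
    lr_decay_factor: float = 1.0
    val_interval: int = 10
    early_stop_dice: float | None = None  # stop when train soft Dice exceeds this
    seed: int = 0


@dataclass
class TrainingLog:
    losses: list = field(default_factory=list)
    val_dice: list = field(default_factory=list)  # (step, dice)
    best_step: int = -1


def _soft_dice(p, g):
    c = losses.soft_confusion(p, g)
    denom = 2 * c.tp + c.fn + c.fp
    return 2 * c.tp / denom if denom > 0 else 1.0


def train_step(samples, model_config: UNetConfig, loss_name: str = "tversky",
               loss_params: LossParams = LossParams(smooth=1e-6),
               train_config: TrainConfig = TrainConfig(),
               augment_config: AugmentConfig | None = None,
               val_samples=None):
    """Train one network on (image, label) pairs at the network input shape.

    Returns ``(network, TrainingLog)``.  With validation samples the
    weights of the best-validation step are restored at the end.  Raises
    on an empty training set and aborts on non-finite loss.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("empty training set")
    rng = np.random.default_rng(train_config.seed)
    net = UNet3D(model_config)
    opt = unet.Adam(net.params, lr=train_config.learning_rate)
    log = TrainingLog()
    best = (-1.0, None)
    for step in range(train_config.steps):
        if (train_config.lr_decay_step and step == train_config.lr_decay_step):
            opt.lr = train_config.learning_rate * train_config.lr_decay_factor
        idx = rng.integers(0, len(samples), size=train_config.batch_size)
        grads_acc = None
        loss_acc = 0.0
        dice_acc = 0.0
        for i in idx:
            image, label = samples[i]
            img = np.asarray(image.voxels, dtype=np.float32)
            lab = np.asarray(label.voxels, dtype=np.float64)
            if augment_config is not None:
                img_a, lab_a = augment_sample(img.astype(np.float64), lab > 0.5,
                                              augment_config, rng)
                img = np.clip(img_a, 0.0, 1.0).astype(np.float32)
                lab = lab_a.astype(np.float64)
            prob, tape = net.forward(img, want_grad=True)
            value, dP = losses.loss_and_grad(loss_name, prob, lab, loss_params)
            if not np.isfinite(value):
                raise FloatingPointError(f"training diverged: loss {value} at step {step}")
            grads = net.backward(tape, dP / train_config.batch_size)
            loss_acc += value / train_config.batch_size
            dice_acc += _soft_dice(prob, lab) / train_config.batch_size
            if grads_acc is None:
                grads_acc = grads
            else:
                for k in grads_acc:
                    grads_acc[k] += grads[k]
        opt.step(net.params, grads_acc)
        log.losses.append(float(loss_acc))
        if val_samples and (step + 1) % train_config.val_interval == 0:
            vd = float(np.mean([
                _soft_dice(net.forward(np.asarray(im.voxels, dtype=np.float32)),
                           np.asarray(la.voxels, dtype=np.float64))
                for im, la in val_samples]))
            log.val_dice.append((step + 1, vd))
            if vd > best[0]:
                best = (vd, {k: v.copy() for k, v in net.params.items()})
                log.best_step = step + 1
        if (train_config.early_stop_dice is not None
                and dice_acc >= train_config.early_stop_dice):
            break
    if best[1] is not None:
        net.params = best[1]
    return net, log


@dataclass
class CascadeModel:
    """Both trained networks plus the shared preprocessing settings."""

    step1: UNet3D
    step2: UNet3D
    preprocess_config: PreprocessConfig
    loss_name: str = "tversky"


def scale_bbox_to_grid(bbox: BoundingBox3D, from_shape, to_shape) -> BoundingBox3D:
    """Map a voxel-index box between grids of different resolution.

    The lower bound rounds down and the upper bound rounds up (outward),
    so anatomy at the box border is never truncated.
    """
    ratios = [t / f for f, t in zip(from_shape, to_shape)]
    lower = tuple(int(np.floor(l * r)) for l, r in zip(bbox.lower, ratios))
    upper = tuple(min(int(np.ceil(u * r)), int(t))
                  for u, r, t in zip(bbox.upper, ratios, to_shape))
    return BoundingBox3D(lower, upper)


def predict_single_step(ct: CTVolume, step1_network: UNet3D,
                        config: PreprocessConfig) -> BinaryMask:
    """Whole-volume prediction mapped back to the original grid."""
    image, _ = make_step1_sample(ct, None, config)
    prob = step1_network.forward(np.asarray(image.voxels, dtype=np.float32))
    low = BinaryMask(prob >= config.binarize_threshold,
                     spacing=image.spacing, origin=image.origin)
    full = preprocess.resample_mask(low, ct.shape)
    return BinaryMask(full.voxels, spacing=ct.spacing, origin=ct.origin)


def predict_two_step(ct: CTVolume, model: CascadeModel) -> BinaryMask:
    """Step-1 localization, step-2 refinement, embedded into the input grid.

    Raises :class:`RegionNotFoundError` when step 1 predicts no
    foreground -- there is deliberately no silent fallback.
    """
    cfg = model.preprocess_config
    image, _ = make_step1_sample(ct, None, cfg)
    prob1 = model.step1.forward(np.asarray(image.voxels, dtype=np.float32))
    fg = prob1 >= cfg.binarize_threshold
    if not fg.any():
        raise RegionNotFoundError("region of interest not found: empty step-1 prediction")
    bbox_low = preprocess.compute_bounding_box(fg)
    bbox = scale_bbox_to_grid(bbox_low, cfg.target_shape, ct.shape)
    bbox = preprocess.pad_bounding_box(bbox, cfg.bbox_margin, ct.shape)
    ct_crop = preprocess.crop_to_bbox(ct, bbox)
    crop_image, _ = make_step1_sample(ct_crop, None, cfg)
    prob2 = model.step2.forward(np.asarray(crop_image.voxels, dtype=np.float32))
    low = BinaryMask(prob2 >= cfg.binarize_threshold,
                     spacing=crop_image.spacing, origin=crop_image.origin)
    crop_mask = preprocess.resample_mask(low, ct_crop.shape)
    crop_mask = BinaryMask(crop_mask.voxels, spacing=ct.spacing, origin=ct_crop.origin)
    return preprocess.embed_prediction(crop_mask, bbox, ct.shape,
                                       spacing=ct.spacing, origin=ct.origin)
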