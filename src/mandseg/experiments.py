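"""Desk-scale cascade study on synthetic phantoms.

This module wires the whole pipeline together at a size a single CPU can
train: 64^3 phantoms, 48^3 network inputs, depth-3/base-8 networks and
the Tversky objective (alpha = 0.3, beta = 0.7).  It trains step-1 and
step-2 networks on 40 phantoms, predicts on 8 held-out phantoms in both
single-step and two-step mode, scores every prediction with the full
metric suite, and compares the two-step model against the 250-HU
threshold baseline on the artifact-bearing cases.

The study is the package's end-to-end regression target; the acceptance
script reruns it from scratch.  All randomness derives from one master
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import cascade, metrics, preprocess
from .cascade import CascadeModel, TrainConfig
from .losses import LossParams
from .metrics import EvaluateConfig
from .phantom import PhantomSpec, generate_dataset
from .postprocess import postprocess_prediction
from .unet import UNetConfig

__all__ = ["StudyConfig", "run_study", "run_replicates"]


@dataclass
class StudyConfig:
    """Desk-scale study conditions."""

    n_train: int = 40
    n_test: int = 8
    phantom: PhantomSpec = field(default_factory=lambda: PhantomSpec(grid_shape=(64, 64, 64)))
    artifact_fraction: float = 0.5
    edentulous_fraction: float = 0.2
    target_shape: tuple[int, int, int] = (48, 48, 48)
    bbox_margin: int = 5  # at the 64^3 phantom grid
    model: UNetConfig = field(default_factory=lambda: UNetConfig(depth=3, base_channels=8))
    loss_name: str = "tversky"
    loss_params: LossParams = field(default_factory=lambda: LossParams(alpha=0.3, beta=0.7, smooth=1e-6))
    train: TrainConfig = field(default_factory=lambda: TrainConfig(
        steps=100, batch_size=1, learning_rate=3e-2,
        lr_decay_step=70, lr_decay_factor=0.2))
    n_surface_samples: int = 10_000
    threshold_hu: float = 250.0


def _derive(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence([int(seed), salt]).generate_state(1)[0] % (2 ** 31))


def run_study(seed: int, config: StudyConfig | None = None) -> dict:
    """One full train/evaluate cycle; returns per-case records and summary means."""
    cfg = config or StudyConfig()
    pre = preprocess.PreprocessConfig(target_shape=cfg.target_shape,
                                      bbox_margin=cfg.bbox_margin)

    train_data, _ = generate_dataset(cfg.n_train, cfg.phantom, _derive(seed, 1),
                                     artifact_fraction=cfg.artifact_fraction,
                                     edentulous_fraction=cfg.edentulous_fraction)
    test_data, test_manifest = generate_dataset(cfg.n_test, cfg.phantom, _derive(seed, 2),
                                                artifact_fraction=cfg.artifact_fraction,
                                                edentulous_fraction=cfg.edentulous_fraction)

    s1 = [cascade.make_step1_sample(ct, m, pre) for ct, m in train_data]
    s2 = [cascade.make_step2_sample(ct, m, pre) for ct, m in train_data]

    import dataclasses
    model_cfg_1 = dataclasses.replace(cfg.model, seed=_derive(seed, 3))
    model_cfg_2 = dataclasses.replace(cfg.model, seed=_derive(seed, 4))
    tc1 = dataclasses.replace(cfg.train, seed=_derive(seed, 5))
    tc2 = dataclasses.replace(cfg.train, seed=_derive(seed, 6))
    net1, log1 = cascade.train_step(s1, model_cfg_1, cfg.loss_name, cfg.loss_params, tc1)
    net2, log2 = cascade.train_step(s2, model_cfg_2, cfg.loss_name, cfg.loss_params, tc2)
    model = CascadeModel(step1=net1, step2=net2, preprocess_config=pre,
                         loss_name=cfg.loss_name)

    ev = EvaluateConfig(n_surface_samples=cfg.n_surface_samples, seed=_derive(seed, 7))
    cases = []
    for i, (ct, gt) in enumerate(test_data):
        record = {"index": i, "artifacts": test_manifest.records[i]["artifacts"]}
        ref_mesh = postprocess_prediction(gt, ev.postprocess)

        single = cascade.predict_single_step(ct, net1, pre)
        rep_s = metrics.evaluate(single, gt, ev, ref_mesh=ref_mesh)
        record["single"] = rep_s.as_dict()

        try:
            two = cascade.predict_two_step(ct, model)
            rep_t = metrics.evaluate(two, gt, ev, ref_mesh=ref_mesh)
            record["two_step"] = rep_t.as_dict()
        except cascade.RegionNotFoundError:
            record["two_step"] = None

        baseline = preprocess.threshold_segment(ct, cfg.threshold_hu)
        record["baseline_dsc"] = metrics.dice_coefficient(baseline, gt)
        cases.append(record)

    def mean_of(mode, key):
        vals = [c[mode][key] for c in cases if c[mode] is not None]
        vals = [v for v in vals if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")

    artifact_cases = [c for c in cases if c["artifacts"] and c["two_step"] is not None]
    summary = {
        "two_step_mean_dsc": mean_of("two_step", "dsc"),
        "single_step_mean_dsc": mean_of("single", "dsc"),
        "two_step_mean_asd": mean_of("two_step", "asd"),
        "single_step_mean_asd": mean_of("single", "asd"),
        "two_step_mean_hd95": mean_of("two_step", "hd95"),
        "single_step_mean_hd95": mean_of("single", "hd95"),
        "two_step_mean_ccd": mean_of("two_step", "ccd"),
        "two_step_mean_bb_iou": mean_of("two_step", "bb_iou"),
        "step1_mean_bb_iou": mean_of("single", "bb_iou"),
        "baseline_mean_dsc": float(np.mean([c["baseline_dsc"] for c in cases])),
        "n_artifact_cases": len(artifact_cases),
        "artifact_model_beats_baseline": bool(all(
            c["two_step"]["dsc"] > c["baseline_dsc"] for c in artifact_cases)),
        "two_step_failures": int(sum(c["two_step"] is None for c in cases)),
        "final_train_loss_step1": float(log1.losses[-1]),
        "final_train_loss_step2": float(log2.losses[-1]),
    }
    return {"seed": int(seed), "cases": cases, "summary": summary}


def run_replicates(base_seed: int, n_seeds: int = 5,
                   config: StudyConfig | None = None) -> dict:
    """Repeat the study over independent seeds and tally the outcome conditions."""
    results = [run_study(_derive(base_seed, 100 + i), config) for i in range(n_seeds)]
    summaries = [r["summary"] for r in results]
    passes = {
        "dsc": sum(s["two_step_mean_dsc"] >= 85.0 for s in summaries),
        "bb_iou": sum(s["step1_mean_bb_iou"] >= 70.0 for s in summaries),
        "asd": sum(s["two_step_mean_asd"] < s["single_step_mean_asd"] for s in summaries),
        "artifact": sum(s["artifact_model_beats_baseline"] for s in summaries),
    }
    return {"replicates": results, "passes": passes, "n_seeds": n_seeds}
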