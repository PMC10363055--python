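# mandseg

Coarse-to-fine mandible segmentation from CT, with a full
surface-distance evaluation suite and synthetic phantoms for end-to-end
testing without patient data.

Automatic segmentation of the lower jaw from head-and-neck CT is a
prerequisite for planning mandibular reconstruction surgery.  Two things
make it hard: the mandible occupies only a small part of the scan (a
severe foreground/background imbalance), and dental metal produces
ray-shaped streak artifacts that corrupt bone boundaries — a simple
Hounsfield threshold happily segments the streaks along with the bone.

`mandseg` implements a two-step cascade of 3D U-Nets: a first network
segments the whole volume at low resolution only to *localize* the jaw;
a second network segments the full-resolution crop of that bounding box,
resampled to the same input size, and its prediction is embedded back
into the original grid.  Training uses overlap-based objectives built
from soft confusion counts (TP = Σ p·g, FN = Σ (1−p)·g, FP = Σ p·(1−g)):

    DL  = 1 − 2TP / (2TP + FN + FP)                 (Dice loss)
    TL  = 1 − TP / (TP + α·FN + β·FP)               (Tversky, α=0.3, β=0.7)
    FTL = TL^γ                                      (Focal Tversky, γ=4/3)

Predictions become surfaces via binary erosion, Gaussian smoothing and
marching cubes, and are scored with five metrics: Dice coefficient
(DSC), one-directional average surface distance (ASD), 95th-percentile
Hausdorff distance (95HD), caudolateral curve distance (CCD — distance
between polylines tracing the lower-outer jaw rim, the contour that
matters for reconstruction planning) and bounding-box IoU (localization
quality).  Model comparisons use paired t-tests with Holm–Šídák
correction.

Because clinical CT cannot ship with the code, the package includes a
deterministic phantom generator: horseshoe-shaped mandible proxies with
thin condylar/coronoid prongs and optional teeth, painted in realistic
HU with partial-volume blur and noise, plus metal seeds casting bright
and dark streaks that corrupt the image but never the ground truth.
Every pipeline stage is trained and tested against these phantoms.

The 3D U-Net itself is implemented directly on NumPy (GEMM-based
convolutions with hand-derived, finite-difference-verified backprop), so
the whole pipeline trains on a single CPU at desk scale.

See `docs/methods.md` for models, parameters and design rationale.

## Worked example

```python
from mandseg.experiments import StudyConfig, run_study

result = run_study(seed=1)           # ~3 minutes on one CPU
s = result["summary"]
print(f"two-step DSC      {s['two_step_mean_dsc']:.1f} %")
print(f"single-step DSC   {s['single_step_mean_dsc']:.1f} %")
print(f"two-step ASD      {s['two_step_mean_asd']:.3f} mm")
print(f"single-step ASD   {s['single_step_mean_asd']:.3f} mm")
print(f"step-1 BB IoU     {s['step1_mean_bb_iou']:.1f} %")
print(f"threshold baseline DSC {s['baseline_mean_dsc']:.1f} %")
```

This generates 40 training and 8 held-out phantoms (64³, half with
metal artifacts), trains both cascade steps (depth-3/base-8 U-Nets, 48³
inputs, Tversky loss) and evaluates the held-out cases.  Output from the
run above:

```
two-step DSC      93.1 %
single-step DSC   90.5 %
two-step ASD      0.130 mm
single-step ASD   0.181 mm
step-1 BB IoU     94.5 %
threshold baseline DSC 83.5 %
```

Read: the refinement step lifts Dice and cuts the mean surface error by
roughly a third relative to a single low-resolution pass; the step-1
bounding box overlaps the true box by ~95%, so the crop is trustworthy;
and the trained model clearly beats the 250-HU threshold baseline,
which cannot reject streak artifacts.

The same pieces are available individually — `mandseg.phantom`
(synthetic data), `mandseg.cascade` (training/inference),
`mandseg.metrics` (evaluation), `mandseg.postprocess` (mask → STL) — and
through a thin CLI:

```sh
mandseg phantom --n 10 --seed 1 --out data/
mandseg train --step 1 --loss tversky --data data/ --seed 1 --out step1.npz
mandseg predict --mode two-step --input case_ct.nii.gz --model models/ \
        --output pred.nii.gz --stl pred.stl
mandseg evaluate --pred pred.nii.gz --gt gt.nii.gz
```

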