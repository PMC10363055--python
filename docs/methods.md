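# Methods

## Problem and pipeline

`mandseg` segments the mandible (lower jaw) from head-and-neck CT and
turns the voxel prediction into a surgical-planning-grade surface mesh.
The pipeline is a coarse-to-fine cascade of two independently trained 3D
U-Nets:

1. **Step 1 (localization).** The whole CT volume is clipped to
   [−1024, 3071] HU, mapped linearly onto [0, 1], down-sampled with
   third-degree spline interpolation to the fixed network input size, and
   segmented at low resolution.  Only the bounding box of this
   prediction is used downstream.
2. **Step 2 (refinement).** The full-resolution volume is cropped to the
   (padded) box, resampled to the same input size — now at much higher
   effective resolution because the jaw occupies only part of the field
   of view — and segmented again.  The refined prediction is mapped back
   to the crop's native grid (linear interpolation of the 0/1 field,
   threshold 0.5) and embedded into the original volume.

During **training**, step 2 sees crops of the *ground-truth* boxes;
during **inference** it sees step-1 boxes.  Inference never reads the
ground truth (the predict functions do not accept one), and an empty
step-1 prediction is a hard `RegionNotFoundError` rather than a silent
fallback.  Bounding boxes mapped between grids round the lower bound
down and the upper bound up, so anatomy at the border is never cut off.

## Network and objectives

The U-Net uses two 3×3×3 same-padding convolutions per resolution level
(instance normalization + leaky rectifier after each), 2×2×2 max-pooling
down, 2×2×2 up-convolutions with skip concatenation up, and a 1×1×1
convolution with a logistic output.  Input shapes must be divisible by
2^(depth−1).  Defaults: depth 4 / 16 base channels for full-scale
configuration, depth 3 / 8 base channels for desk-scale runs.

The network is implemented directly on NumPy with hand-derived backward
passes (convolutions as per-offset GEMM accumulations against shifted
views of the padded input; this is the memory-traffic-minimal layout for
small channel counts on CPU).  Gradients are exact and verified against
finite differences in the test suite.  Training uses Adam.

Three objectives are provided, all functions of soft confusion sums
TP = Σ p·g, FN = Σ (1−p)·g, FP = Σ p·(1−g):

* Dice loss `DL = 1 − 2TP/(2TP + FN + FP)`;
* Tversky loss `TL = 1 − TP/(TP + αFN + βFP)` with defaults α = 0.3,
  β = 0.7;
* Focal Tversky loss `FTL = TL^γ` with γ = 4/3, which steepens the loss
  surface for poorly overlapping examples (TI < 0.5).

As printed above, α weighs the false negatives and β the false
positives.  Descriptions of the Tversky index elsewhere sometimes attach
the symbols the other way around; both conventions are reachable by
swapping the two values, and the package implements the formula exactly
as written here.  A smoothing term (default 1e−6 during training, 0 in
unit tests) keeps the loss defined on empty-foreground crops.  Losses
are computed per batch item and averaged.

## Preprocessing and augmentation choices

* Normalization divides by 4095 = 3071 − (−1024), so the clip endpoints
  map exactly to 0 and 1.
* Resampling is cell-centered (`new voxel center i ↦ (i+0.5)·ratio − 0.5`)
  so physical extent is preserved and spacing rescales by the shape
  ratio.  Spline boundary handling makes the outermost ~4 voxels
  slightly inexact for non-constant fields; interior values reproduce
  constant and linear fields to well below 1e−6.
* Labels are resampled with linear interpolation + 0.5 threshold, never
  cubic splines (overshoot would create spurious labels).
* `threshold_segment` uses an inclusive ≥, matching common CT tools.
* Eight augmentation families (mirror, translate, blur, additive noise,
  transient down-sampling, scale, rotate, elastic) are applied in that
  fixed order; spatial transforms act identically on image and label,
  intensity transforms on the image only.  Out-of-field voxels are
  filled with 0 (normalized air).  Randomness is separated from geometry
  by a serializable *transform plan*, so any draw can be replayed.

## Post-processing

Prediction → mesh: one binary erosion with the minimal 6-connected cross
element (compensates the one-voxel dilation that surface-to-voxel
conversion of training labels introduces, without destroying the thin
condylar/coronoid processes), Gaussian smoothing of the eroded 0/1 field
(σ = 1 voxel), marching cubes at iso-level 0.5.  Vertices are in world
mm via spacing and origin.

## Evaluation metrics

* **DSC** on voxel masks, percent.  Optionally computed inside the
  padded ground-truth box (the protocol used when predictions are
  defined on crops).
* **ASD** is one-directional: area-weighted random points sampled on the
  *test* mesh, exact point-to-triangle distance to the *reference* mesh.
  Exactness at scale comes from a pruned search: for each point, every
  face whose centroid lies within (distance to nearest mesh vertex +
  max centroid-to-corner radius) is checked; a face closer than the
  nearest-vertex upper bound necessarily lies in that ball.  Default
  100 000 samples with a fixed seed; two seeds agree within ~2% on
  phantom-scale meshes.
* **95HD** is the 95th percentile (linear interpolation between order
  statistics) of the same one-directional distance set; a symmetric
  variant is behind a flag.
* **CCD**: both meshes are reduced to their largest connected component;
  vertices are binned by azimuth around the axial-plane centroid over
  the occupied angular span; each bin contributes the caudal-most vertex
  among its radially outermost decile; the ordered polyline is smoothed
  with a 5-point moving average, and the mean point-to-polyline distance
  (prediction → reference) is reported.  This is a deliberately
  simplified geometric extractor of the caudolateral rim; it preserves
  the metric's intent without the landmark-individualization machinery
  used on clinical data, and is validated against the analytic rim of a
  half-torus solid.
* **BB IoU** of tight voxel bounding boxes, percent — the quality of the
  localization step.

Statistics: two-sided paired t-tests; Holm–Šídák step-down correction
(`1 − (1−p)^(m−i+1)` with monotonicity enforcement, via statsmodels)
applied per metric; four significance classes at 0.05 / 0.01 / 0.001.

## Phantoms

The generator emulates the features of the clinical data that the
pipeline actually exercises: a horseshoe bony arch (half-torus) joined
to two vertical rami, each carrying two thin prongs (condylar/coronoid
proxies — exactly the structures single-step segmentation struggles
with); optional hemispherical tooth bumps (count 0 = edentulous, drawn
per sample); tissue classes air ≈ −1000 HU, soft-tissue envelope
≈ +40 HU, bone ≈ +1200 HU; a partial-volume blur (σ = 0.8 voxel)
standing in for the scanner point-spread function; additive Gaussian HU
noise (σ = 40 HU); lateral spacing drawn from [0.2, 0.9] mm and axial
from [0.5, 1.5] mm (the axial range is narrowed from the clinical
[0.1, 4] mm so a desk-scale grid still resolves the arch; the full range
remains configurable).  The arch occupies roughly a third of the lateral
field of view, mirroring how the mandible sits inside a head-and-neck
scan — this is what makes the cascade's crop step worthwhile.  Metal is
simulated as seeds (> 2500 HU) on the cranial surface of the label that
cast alternating bright/dark rays through the axial plane with distance
decay; streaks corrupt only the CT image, never the label, because
clinical ground truths have artifacts removed.  The streak model is
geometric ray casting, not a sinogram simulation: the pipeline only
needs HU-plausible confounders above and below bone thresholds.

Everything derives from explicit seeds via `numpy.random.SeedSequence`;
datasets are bit-reproducible from their manifest.

What the phantoms do *not* model: real cranial anatomy (skull base,
hyoid, vertebrae), beam hardening physics, scanner-specific noise
texture, or inter-observer ground-truth variability.  Passing the
desk-scale study therefore demonstrates that the pipeline's mechanics —
localization, crop-resolution gain, artifact rejection relative to
thresholding — work end to end, not that clinical-grade accuracy is
reached on patient data.

## Desk-scale study

The end-to-end regression (`mandseg.experiments.run_study`) trains both
cascade steps (depth 3, base 8, 48³ inputs, Tversky α = 0.3 / β = 0.7)
on 40 phantoms at 64³ native resolution and evaluates on 8 held-out
phantoms (50% with metal artifacts, 20% edentulous).  Training runs 100
Adam steps at learning rate 3e−2 (×0.2 after step 70) with batch size
1 — chosen for the NumPy network, where that schedule reaches a stable
training plateau on phantom data; the clinical-scale default in the
config is the conventional 1e−4.  The crop margin is 5 voxels at the
64³ grid: enough crop context around the bone measurably improves
step-2 boundary accuracy, and the margin also absorbs step-1
localization error.  Evaluation uses 10 000 surface samples per mesh
pair.  The study repeats over 5 independent seeds in the acceptance
suite; `scripts/acceptance.py` reruns a single replicate and reports its
summary quantities.

The post-processing round trip (erode → smooth → marching cubes →
voxelize ≈ eroded mask) is checked on a 96³ phantom.  This is a scale
constraint, not an implementation one: at 48³ the eroded arch is only
~2–3 voxels thick, below the σ = 1 smoothing scale, so the 0.5
iso-surface cannot recover it; at 96³, where cortical thickness is
proportioned like clinical data, the round trip agrees to ~98% Dice.

## Known limitations

* The NumPy network is desk-scale; the 144³ clinical configuration is
  expressible but impractically slow to train on one CPU.
* The caudolateral curve extractor assumes a roughly horseshoe-shaped
  largest component; on fragmented predictions the metric is flagged
  rather than computed, which mirrors how disconnected predictions are
  handled upstream.
* STL vertex welding uses exact bit-equality — sufficient for
  marching-cubes output, not for meshes from lossy sources.
* DICOM reading supports axis-aligned axial series only; oblique
  orientations are rejected rather than resampled.
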