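# Methods

`scoutreid` implements patient re-identification for trunk scout CT
(localizer) images: given a follow-up scout image whose metadata may be
lost or wrong, find the enrolled baseline image of the same patient by
comparing deep feature vectors with cosine similarity.  This note
documents the models, the synthetic phantom used to exercise them, the
numerical choices, and what the desk-scale experiments do and do not
show.

## The identification pipeline

1. **Preprocessing** (`io_preproc`).  Every image is resampled to
   2.0 × 2.0 mm² pixel spacing with bicubic interpolation, the central
   384 rows × 256 columns are cropped (zero-padded when the image is
   smaller), and the bit depth is linearly rescaled to 8 bits using the
   image's own minimum and maximum.  Output dimensions of the resampling
   follow `round(dim · spacing_in / spacing_target)` per axis, so the
   physical extent is preserved within one target pixel.  The crop
   window is floor-biased on odd excess; a constant image maps to all
   zeros rather than dividing by zero.  Whether the 8-bit window should
   be per-image or global is an open choice; per-image min–max is
   implemented and flagged in `PreprocessConfig.per_image_window`.

2. **Feature extraction** (`embedder`).  A backbone maps the
   384 × 256 single-channel image to a fixed-dimension feature vector
   (1280-d for the full-scale EfficientNetV2-L configuration the method
   was designed around; the backbone is a pluggable contract).  During
   training a projection head (linear → ReLU → batch norm → linear) and
   an AdaCos cosine-softmax metric layer with one class per training
   patient are attached.  At inference the head is dropped by default
   and the backbone feature vector is the patient representation.

3. **Matching** (`matcher`).  Baseline embeddings (one per patient, the
   earliest exam) form the gallery.  Queries are ranked by cosine
   similarity; the top-ranked gallery patient is the answer, and top-K
   lists support alerting and CMC evaluation.

## AdaCos

The metric layer keeps `C` unit-norm class weight vectors and scales
cosine logits by a factor `s` re-estimated from batch statistics every
training step:

    s₀     = √2 · ln(C − 1)
    B_avg  = meanᵢ Σ_{k≠yᵢ} exp(s · cos θᵢₖ)      (previous s)
    θ_med  = medianᵢ θᵢ,yᵢ
    s      = ln(B_avg) / cos(min(π/4, θ_med))

so no manual scale or margin tuning is needed.  `C < 3` is rejected
(`s₀` degenerates), `s` is asserted finite and positive after every
update, and the class weights are re-projected to the unit sphere after
each optimizer step.  The loss is label-smoothed cross entropy,
`t = (1 − ε)·onehot + ε/C` with ε = 0.05.

Training defaults follow the published configuration: batch size 20,
cosine learning-rate decay without warmup, momentum-SGD (momentum 0.8,
weight decay 0.002).  A generic two-step sharpness-aware wrapper
(perturb by ρ·g/‖g‖ with ρ = 2.0, then descend with the perturbed-point
gradient) is available via `optimizer="sam"`; the element-wise adaptive
variant's exact normalization is not published, so plain momentum SGD is
the desk-scale default.

## Augmentation

Training images pass through four sequential layers: random perspective,
random rotation, RandomTransversalScaling, and a centered crop.
RandomTransversalScaling emulates table-height variability: with
probability `p` (default 0.25) the image width is rescaled by
`s ~ Uniform[1/f, f]` (default `f` = 1.04) with bicubic interpolation
while the height magnification stays fixed, then the image is
re-center-cropped/padded to its original width.  The reciprocal range
reflects tables positioned above or below the isocenter (symmetric in
the multiplicative sense); a linear range `[2−f, f]` is available via
`transversal_sampling="linear"`.  Perspective and rotation magnitudes
are not published; conservative defaults (distortion 0.1 at p = 0.5,
±3° at p = 0.5) are used, with bilinear interpolation since these
layers' interpolation is unspecified and the magnitudes are small.
Flips are never applied: a mirrored trunk is a clinically meaningful
error.  Augmentation operates on the preprocessed 8-bit image (whether
the original pipeline augments before or after the 8-bit rescale is
unstated; after is implemented).

## The desk-scale reference backbone

No GPU autodiff stack is assumed: the package carries a compact NumPy
layer library (`_nn`) with explicit gradients — im2col convolution,
batch normalization, average pooling, linear, L2 normalization, momentum
SGD, a sharpness-aware wrapper, and a cosine schedule — all
gradient-checked against numerical differentiation in the test suite.
The reference backbone is a 4× average-pooling stem followed by four
3 × 3 conv blocks with 2× pooling and global average pooling, producing
a 64-d feature (configurable).  The final block deliberately omits the
ReLU: rectified channels are all-positive and their common mode would
dominate cosine similarity.

The input adapter equalizes each image's histogram before
standardization.  Vendors apply distinct monotone tone curves (contrast
correction, dynamic-range compression); histogram equalization maps any
monotone remapping of the same scene to nearly the same input, so the
small backbone does not have to spend capacity learning tone-curve
invariance.  The full-scale configuration would feed raw 8-bit images
and learn this invariance from data.

## The phantom

The generator produces anterior-view trunk projections from a sum of
soft-edged geometric primitives — fast and controllable, not
anatomically realistic:

* **Identity (stable per patient):** torso half-widths at
  shoulder/waist/pelvis (quadratic profile), torso height, lung area,
  vertebral periodicity, pelvis ellipse aspect, an optional implant, and
  a smooth patient-specific texture field defined in patient coordinates
  (so it is consistent under any vendor grid or magnification).
* **Vendor (domain shift):** the S-like scanner renders at
  2.0 × 2.0 mm on a 560 mm field of view with a gamma + log-compression
  tone curve; the G-like scanner at 0.55 × 0.60 mm on 530 mm with a
  sigmoid contrast curve.  Table-height habits differ by vendor
  (mean +3 mm vs −6 mm, SD 14 mm), mirroring the published per-device
  table-height statistics, so cross-vendor pairs carry a systematic
  width-magnification mismatch on top of the contrast shift.
* **Geometry:** with source-to-isocenter distance d₀ = 600 mm (SID
  1000 mm), a table offset `dh` scales the projection width by
  `s(dh) = d₀/(d₀ − dh)` — ≈ 1.04 at dh ≈ +23 mm — while the
  longitudinal axis, swept by table feed, is unaffected.  `|dh| ≥ d₀`
  is rejected as degenerate.
* **Per-exam nuisances:** scan-range shift, lung inflation, intestinal
  gas blobs, arm position and additive noise, fired with configurable
  rates (defaults 0.50/0.40/0.325/0.225, the relative ordering of the
  published top error reasons).

All randomness flows from explicit seeds (patient identity from
`(master_seed, patient_id)` via CRC-32, exam state from
`(seed, patient_id, exam_index)`); renders are bit-reproducible.
`silhouette_width_mm` measures the body width by thresholding a row
profile at the half-body attenuation level mapped through the vendor's
tone curve, with subpixel interpolation — vendor-independent up to
discretization, which is what the geometry tests rely on.

What the phantom does **not** model: real anatomy and pathology, organ
motion, X-ray scatter, detector blur, longitudinal growth or weight
change, more than two vendors, and view positions other than frontal.
Passing tests therefore show that the pipeline learns and evaluates the
*structure* of the problem (stable identity + vendor shift + geometric
magnification), not that it would reach any particular accuracy on
clinical data.

## Desk-scale study conditions

The paired augmentation experiment (`experiment.run_augmentation_comparison`)
uses 96 phantom patients per cohort: 36 training patients with three
exams (two train, one validation — the train/validation split is
disjoint by image but shares patients), and 60 test patients with one
baseline and one follow-up exam each.  Vendors are assigned per exam at
random, so roughly half the follow-up queries are cross-vendor; the
same-vendor/different-vendor stratification then has ≈30 queries per
group.

The experiment runs on a 4-mm working grid (192 × 128 crop) with a 2×
stem pool, which feeds the backbone the same effective 8-mm input as
the full 2-mm / 384 × 256 pipeline with its 4× stem — the network
geometry is identical, the augmentation and I/O are four times
cheaper.  The desk backbone width is 6 (channels 6/12/24, 64-d
feature).  Training runs 150 epochs (~900 optimizer steps) at a
learning rate of 0.02 → 0.002; the tiny backbone needs a larger rate
and longer schedule than the published full-scale 0.005 → 0.0005,
which remains the `TrainConfig` default.  The epoch count is the
model-selection knob: training runs the fixed budget and the final
weights are deployed.  Three seeds are run per condition and medians
reported; the two conditions of a pair share the cohort, so the
comparison is paired.  In these runs the per-epoch validation
diagnostics are switched off (``track_validation=False``).

Desk-scale training outcomes are chaotic: imperceptible input
perturbations shift individual stratified accuracies by ±0.1 or more,
which is why the protocol reports medians over three seeded paired
runs rather than any single run.

**Overtraining probe** (`experiment.run_overtraining_probe`): a
deliberately overextended run — 24 patients, 400 epochs, augmentation
disabled — tracking the genuine/impostor cosine statistics of the
*probe* identities (test patients, disjoint from training) every 20
epochs.  Augmentation is removed because at desk scale its noise masks
the memorization effect the probe is after.  The training loss
plateaus well before the halfway point, so the drift of the probe
impostor mean between the halfway checkpoint and the end isolates what
over-training does to unseen identities: it drifts upward, toward the
genuine level.

These sizes were chosen to keep a full paired comparison within minutes
on one CPU core while leaving enough queries per stratum for accuracy
differences of a few percentage points to be expressible.

## Evaluation and statistics

`topk_accuracy` / `cmc_curve` rank with stable ties (ascending gallery
index) and are cross-checked against a brute-force full-sort oracle on
random instances.  Queries whose patient is not enrolled are excluded
from accuracy, warned about, and listed — never silently dropped.
`stratified_eval` reports per-(baseline-vendor, follow-up-vendor) cells,
pooled same/different-vendor groups, genuine/impostor score statistics,
and the failing queries with their top scores.

The unpaired two-proportion Z-test (pooled variance) and McNemar's test
(continuity-corrected χ² by default, exact binomial when b + c < 25)
are delegated to statsmodels behind the package's own API and verified
against closed forms to 1e-10.  p-values are reported raw; no
multiple-testing adjustment is applied.

## Known limitations

* The desk-scale backbone is orders of magnitude smaller than the
  full-scale configuration; its absolute accuracies on the phantom are
  not comparable to published clinical numbers and are not meant to be.
* Histogram equalization in the input adapter is a desk-scale
  harmonization choice, not part of the published preprocessing chain.
* The exam-to-vendor assignment process is unknown in the source
  setting; the phantom exposes it as a policy (`random-exam` default,
  `fixed-patient` alternative).
* DICOM support covers single-frame secondary-capture-like objects with
  PixelSpacing and TableHeight tags; VOI LUTs and multi-frame objects
  are out of scope.
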