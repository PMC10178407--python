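# Methods

## Problem and pipeline

The package assesses body-surface wounds from single nadir RGB photographs in
two coupled steps:

1. **Segmentation.** A convolutional encoder–decoder produces a per-pixel
   wound probability map; thresholding at 0.5 gives the binary wound mask.
2. **Area estimation.** A flat reference shape ("prior graphic") of known
   physical area S_pi (cm²) is photographed at a ladder of shooting heights
   h₁…h_n (mm). Each height yields a pixel count λ, and a least-squares fit
   λ = f(h) converts any wound pixel count λ_w captured at an in-range
   height h_i into physical area:

       S_w = S_pi · λ_w / f(h_i)

   Heights outside [h₁, h_n] are refused: the curve is an interpolation,
   never an extrapolation.

## Segmentation network

The encoder is a short-term dense concatenate (STDC) backbone. A ConvX is
convolution + batch normalisation + ReLU. Stages 1–2 are single stride-2
ConvX units; stages 3–5 are chains of STDC blocks whose first block has
stride 2, so the spatial side after stage s is `input_side / 2^s`. An STDC
block runs four ConvX units emitting N/2, N/4, N/8, N/8 channels (kernel 1
for the first, 3 after; with stride 2 the stride sits in the second unit and
the first unit's output is average-pooled 3×3/2 so all parts align) and
concatenates every intermediate output into exactly N channels — multi-scale
receptive fields at a fixed channel budget.

The decoder follows the BiSeNet context-path recipe: a globally pooled
context vector, attention-refine modules (ARM: global pool → 1×1 conv → BN →
sigmoid channel gate) on stages 4 and 5, stepwise bilinear upsampling, and a
feature-fusion module (FFM: concatenate, 1×1 ConvX, channel-attention
residual) joining the 1/8-resolution stage-3 feature with the decoder
counterpart. Coordinate attention — separate row and column pooling, a
joint reduced-channel transform, then per-(channel,row) and
per-(channel,column) sigmoid gates multiplied into the input — is applied
before and after the FFM when enabled. All three attention modules are
multiplicative gates in (0,1), so they preserve shape and never amplify
feature magnitude.

Two capacity variants follow the published configurations of the backbone
family the names come from: 813 uses (2,2,2) STDC blocks in stages 3–5,
1446 uses (4,5,3). Default stage channels are (32, 64, 256, 512, 1024) with
a 512×512 working resolution; arbitrary input resolutions are bilinearly
resized in and the wound-probability map resized back out.

Choices the architecture description left open, fixed here:

* ARM is applied to stages 4 and 5; stage 3 enters through the FFM
  (a config switch `arm_on_stage3` adds the third gate).
* The two coordinate-attention modules do not share weights.
* Coordinate-attention bottleneck reduction defaults to 32 (floor of 4
  channels); it must not exceed the channel count.
* Decoder resampling is bilinear; class scores are softmax-normalised.
* The stage-6 classification tail (ConvX → global average pool → two fully
  connected layers) exists only when `include_classifier=True`; segmentation
  never uses it.

## Training

Loss = cross-entropy + soft dice on the main head, the same on auxiliary
heads over stages 4 and 5, and binary cross-entropy + dice on a detail head
attached to stage 3, all weighted (1, 1, 1) by default. The detail head is
supervised by a multi-scale Laplacian edge map of the mask (scales 1, 2, 4;
threshold 0.1; nearest-edge padding so constant masks produce no response):
shallow features are pushed to encode wound boundaries explicitly.

Optimisation is SGD with momentum 0.9 and weight decay 5·10⁻⁴, initial
learning rate 0.01, batch size 8, polynomial decay `lr·(1−t/T)^0.9` — the
conventional recipe for this architecture family. Training histories are reproducible bit-for-bit under a fixed
seed; the best checkpoint is selected by validation dice. A NaN loss aborts
with a diagnostic rather than continuing.

Augmentation covers rotation by an angle drawn from
0–360° (axis-aligned multiples of 90° use exact array rotation, so the
mask-consistency property is exact there; other angles interpolate — order-1
with reflect padding for the image, order-0 with zero padding for the mask,
keeping masks binary), random cropping of the height or width to a
configurable fraction (default one third), Gaussian noise (σ = 10/255) and
multiplicative brightness in [0.7, 1.3] on the image only. A dataset
expansion helper multiplies a small dataset by a configurable factor
(clinical wound sets are typically enlarged several-fold this way).

## Autodiff engine

No GPU tensor framework is a dependency: the package carries a small
reverse-mode autodiff engine on numpy (`woundseg.nn`) providing exactly the
ops the network needs — conv2d via im2col, batch norm, average pooling,
separable bilinear resampling (matrix form, so its adjoint is a transpose),
channel softmax, concatenation and broadcast arithmetic. Every backward pass
is verified against central finite differences in float64; the network runs
in float32. This keeps the training loop modest: CPU-sized runs use reduced
channel plans and working resolutions (below).

## Evaluation metrics

Confusion counts are exact pixel counts. Recall = TP/(TP+FN); dice =
2TP/(2TP+FP+FN), the harmonic mean of pixel precision and recall; IoU =
TP/(TP+FP+FN), linked by dice = 2·IoU/(1+IoU). mIoU averages per-class IoU
over the (k+1)-class confusion table, excluding classes absent from both
prediction and truth (0/0). Average precision is the pixelwise
all-thresholds step rule (ΣΔR·P over descending distinct scores); mAP is
its mean over evaluated images, skipping images with empty ground truth with
a warning. AUC is the area under the pooled pixel-level ROC curve
(trapezoidal rule), which equals the rank statistic — the probability that a
random wound pixel outscores a random background pixel, ties counted half.
Per-image means are the primary aggregation; metrics are reported as
fractions in [0, 1]. Undefined metrics (empty denominators) are reported as
missing, never as zero. Throughput measurement (images/s) exists as a
diagnostic only — it is hardware-dependent and not an evaluation surface.

## Height calibration

A nadir pinhole camera with focal length f and pixel pitch p images a plane
at distance h at f/(h·p) px/mm, so λ ∝ h⁻² exactly. A polynomial in raw h
cannot track a 5:1 height range of this curve to sub-percent accuracy (a
degree-4 fit leaves >15% relative error even with relative weighting), so
the default model fits a degree-4 polynomial in powers of 1/h — a basis that
contains the true curve — by relative least squares (residuals weighted by
1/λ, since λ spans a 25-fold range and the quantity that matters downstream
is the relative error of λ_i). Two alternatives are exposed: a raw-height
polynomial basis (classic unweighted least squares; exact for polynomial
test data) and the exact-physics model λ = a/h² fitted linearly against
1/h². The fitted curve must be positive over [h₁, h_n], checked on a dense
grid. Wound pixels are always counted at the native capture resolution —
the probability map is resized back to the input image before thresholding —
because the ratio in the area formula presumes prior and wound frames share
one pixel grid.

The minimum-bounding-rectangle baseline (the manual measurement the method
is compared against) is axis-aligned by default; a rotated-minimum-rectangle
option uses the convex hull's minimum rotated rectangle.

## Synthetic data

The clinical datasets and the physical height-platform rig are private, so a
renderer emulates both under an ideal nadir pinhole model. Wound outlines
are star-convex radial curves r(θ) = r₀(1 + Σ aₖcos(kθ+φₖ)) (harmonics
k = 2…5, amplitudes 0.02–0.12) or ellipses; both have closed-form physical
areas, so every mask carries an exact ground truth. The appearance model is
a skin-toned background with a gentle illumination gradient, a reddish wound
texture with radial darkening and speckle, a soft alpha edge from the
rasteriser's coverage fraction, and additive Gaussian noise. Masks are
rasterised at 4× supersampling with an irrational sub-pixel centre offset so
straight edges never align exactly with pixel-centre rows.

Default camera: f = 4 mm, pixel pitch 0.002 mm, 2000×1500 px — fixed,
documented stand-ins for unreported smartphone intrinsics. Calibration
ladders default to a 4 cm² square at 100–500 mm in 10 mm steps (41 frames).
Calibration records carry sub-pixel coverage sums rather than integer
thresholded counts: an axis-aligned square's integer count quantises each
side to whole pixels (~1–2.5% error at the ~80 px sizes reached at 500 mm),
an error no supersampling removes, while the coverage sum tracks the
projected area to ~0.2%. Wound-scene pixel counts stay exact integer mask
counts — irregular boundaries average the quantisation out — and
`count_mask_pixels(mask)` equals the renderer's reported count exactly.

What the renderer does **not** emulate: perspective off-nadir geometry, lens
distortion, 3-D wound curvature and depth, specular highlights, hair,
shadows, and the full appearance diversity of clinical wounds. Passing tests
therefore demonstrate the correctness of the geometry, calibration and
training machinery, not clinical-grade segmentation accuracy.

## CPU-sized run conditions

Tests and the acceptance script scale the problem down while preserving the
capture geometry: a scaled camera (256×192 px, pitch 0.015625 mm) keeps the
default camera's field of view, close-up heights (120–300 mm) give wounds a
realistic share of the frame, and the network runs with stage channels
(8, 16, 32, 64, 128) at working resolutions 64–160 px. The standing runs
are: an overfit sanity run (8 fixed scenes, 300 optimizer steps) and a
pipeline run (50 training scenes, 200 optimizer steps, working resolution
160). At these sizes ground-truth masks recover areas to well under 2%
relative error and network-predicted masks to a mean of about 3%. Numbers
from these runs are computed fresh by `scripts/acceptance.py` and the test
suite; none are stored.

## Known limitations

* The renderer's wounds are star-convex and texturally simple; real wounds
  are not. Segmentation quality numbers on synthetic scenes are upper bounds
  in kind, not predictions of clinical performance.
* The area model assumes nadir capture of a planar wound; oblique imaging
  and curvature are out of scope.
* No pretrained backbone weights ship with the package (none are published);
  `pretrained_path` accepts an externally supplied checkpoint.
* The numpy engine is single-threaded per op and CPU-bound; full-resolution
  (512 px, 1024-channel) training is architecturally supported but slow.
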