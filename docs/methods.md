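# Methods

## Scanner frame and conventions

All geometry lives in a fixed scanner frame: axis 0 is vertical
(anterior-positive, "up"), axis 1 lateral (patient-left positive), axis 2
longitudinal (superior positive); lengths are in mm. The gantry isocenter is
a fixed point of the scanner, represented by its vertical coordinate
`isocenter_y` (0 by default), so "centerline above the gantry center" is a
positive number literally. DICOM readers and writers convert between this
frame and the patient LPS frame; nothing outside `dicom_io` sees a format
dialect.

Synthetic intensities live on a normalized [0, 1] scale snapped to a 4096
level ladder (12-bit, like a CT detector). 4096 is a power of two, so the
integer round trip through DICOM/NIfTI storage is bit-exact in float32.

## The phantom population

A phantom is an ellipsoidal body (semi-axes from the AP and lateral
diameters, longitudinal semi-axis 300 mm) containing two ellipsoidal
air-density lungs (55 % / 34 % of the body's AP / lateral semi-axes, 120 mm
longitudinal semi-axis, centered at ±0.42 lateral semi-axes and 5 % of the
AP semi-axis anterior of the body center), resting above a concave couch
slab, optionally covered by a blanket shell. Region intensities follow a
fixed ledger: background 0, lung 0.15, blanket 0.35, couch 0.55, soft
tissue 0.7. Rendering composites partial-volume (anti-aliased) edges ~3 mm
wide, so sub-voxel geometry is encoded in boundary intensities — this is
what lets the scout view carry sub-pixel width information.

Population parameters are the study conditions of an adult chest cohort:

* diameters (cm): AP ~ N(24.3, 3.6²), lateral ~ N(30.1, 5.3²), sampled
  jointly with correlation 0.7 (adult thoraxes are wider when they are
  deeper; the correlation is a modelling choice, only the marginals are
  cohort-constrained), truncated at ±3 SD with redraw;
* couch-height offset: zero-mean normal whose SD is solved from the
  clinical prevalence "60 % of cases mis-centered by more than 10 mm":
  P(|X| > 10) = 0.6 for X ~ N(0, σ²) gives σ = 10/Φ⁻¹(0.7) = 19.07 mm.
  A mean-bias term is configurable (clinical cohorts run several mm
  positive); the default keeps the offset centered so the prevalence
  calibration is the single constraint.

Couch geometry: a 20 mm thick circular-arc slab (sag radius 800 mm), 400 mm
wide (real couches are narrower than the 480 mm lateral field of view), with
a 10 mm air gap below the body — at the 4 mm desk-scale voxel pitch a
smaller gap bridges to the body after partial-volume rendering and would
merge couch and body into one connected component. The blanket is a
conforming shell (8 mm thick, 8 mm air gap, covering the anterior 80 % of
the body) — an approximation of draping; a blanket in full contact with the
skin is inseparable from the body by intensity thresholding alone.

## Forward projection

The AP localizer is the mean attenuation along the vertical axis of the
rendered volume, giving a (Z × lateral) radiograph. In divergent mode the
lateral axis is additionally magnified about the gantry axis by
`m = SDD / (SDD − h)`, where `h` is the body-center height above the
isocenter and SDD (default 600 mm) the source distance. This single-factor
magnification model is the mechanism by which couch height becomes readable
from a single scout: a raised patient projects wider, and in particular the
couch — whose physical width is a scanner constant — projects at a width
that encodes `m` free of any patient-size confound. Cohort simulation uses
divergent projection by default for exactly this reason; parallel mode is
the projector default for geometric tests.

## Pre-processing

Localizer and volume are cropped to the intersection of their lateral × Z
physical extents (a no-op for synthetic pairs, which share extents),
min–max normalized to [0, 1] per image (a constant image maps to zeros with
a warning rather than NaN), and resized with endpoint-preserving linear
interpolation to fixed matrices — 144 × 64 (lateral × Z) for the localizer
and 184 × 144 × 64 (AP × lateral × Z) for the coronal volume at reference
scale; 48 × 32 and 64 × 48 × 32 at desk scale. In this package's axis order
an axial array read along axis 0 *is* the coronal stack, so reorientation is
the identity permutation, kept explicit in one function so the contract is
testable. A `CropRecord` carries the mm span of each axis (first to last
sample), which, together with endpoint-preserving resizing, makes the
mapping from a network prediction back to scanner-frame mm exact at the
grid corners and linear in between. The cohort split is random, stratified
per scanner id, 80/20 by default.

## The reconstruction network

The synthesis model is a 2D U-Net over the (lateral, Z) plane whose final
layer emits one output channel per AP bin of the coronal volume: the third
dimension is generated as channels, which keeps the stride-2×2 downsampling
a genuinely 2D operation. Each encoder level is conv(3×3, stride 2) +
batch norm + ReLU; the bottleneck applies two stride-1 conv blocks; each
decoder level is nearest-neighbour upsampling, concatenation with the
mirrored encoder feature (the raw input at full resolution), and two conv
blocks; the head is a 3×3 conv block plus a zero-initialized 1×1 conv, so
training starts from a flat volume instead of noise.

Two additions address a failure mode specific to batch-size-1 training:
with a single image per step, batch normalization normalizes *per image*,
which erases exactly the image-global statistics (apparent widths,
brightness) that encode the geometric magnification. First,
squeeze-and-excite style global-context blocks add pooled-feature biases at
the bottleneck and before the head. Second, and decisively, a
vertical-placement head factors *where* the body sits out of the texture
synthesis: a small normalization-free convolutional branch reads the raw
localizer, global-average-pools, and predicts a single scalar — an AP shift
in output-bin units — which is applied to the synthesized volume as a
differentiable channel warp (linear interpolation, edge replication). The
placement scalar gets a short, direct gradient path, and rendering a
translation costs one parameter's worth of learning instead of propagating
through every decoder level. In desk-scale experiments the predicted shift
correlates above 0.9 with the true couch offset after 20 epochs; without
the placement head the same budget recovers almost none of it.

Training: Adam (β₁ = 0.9, β₂ = 0.99), batch size 1, MSE loss (L1
available), no augmentation, no learning-rate schedule; default learning
rate 10⁻³, with 3·10⁻³ used by the desk-scale study. Everything is float32
numpy with manual backpropagation; runs are bit-deterministic for a fixed
data/config/seed triple, and checkpoints (weights + config + a preprocess
configuration hash) reload to identical predictions. Prediction refuses a
checkpoint whose preprocess hash disagrees with the caller's.

## Centerline measurement

The volume is min–max normalized (making the measurement invariant to
affine intensity rescaling), thresholded at `body_threshold` (default
0.65), and 26-connected components are screened by shape: components wider
than 4× their height, or with mid-slice solidity below 0.5, are foreign
objects (couch, blanket); the largest survivor is the body, and per-slice
hole filling brings the lungs inside the mask. The body threshold sits
above the couch's normalized intensity band deliberately: on MSE-trained
reconstructions the blur between couch and body bridges at low thresholds
and drags the posterior limit down by ~10 mm; on crisp volumes the measured
centerline is insensitive to the threshold (verified over 0.25–0.85)
because bounding-box erosion is vertically symmetric. Lungs are the two
largest low-intensity components (< 0.3 normalized, above the lung tissue
level of 0.15/0.7 ≈ 0.21) inside the body; fewer than two triggers a
flagged fallback. One joint bounding box spans both lungs. Bounding boxes
use voxel centers; the centerline is the midpoint of the anterior and
posterior limits, optionally restricted to a longitudinal scan range. A
volume whose body mask touches a lateral or vertical field-of-view boundary
in more than 10 % of its slices is flagged truncated and excluded from
cohort statistics — the automated stand-in for the manual
truncation-artifact exclusion a reader would perform (Z boundaries do not
count; chest scans legitimately cut the torso).

## Metrics and statistics

`BCAP/BCMP/LCAP/LCMP` are exact arithmetic on the measured centerlines with
the sign convention above. Cohort summaries report mean ± SD with a normal
95 % CI (mean ± 1.96·SD/√n), median and IQR, the fraction of absolute
errors strictly above 10 mm and the count above 20 mm. The Mann–Whitney
test uses the exact null distribution when the smaller sample has ≤ 8
observations and no ties, otherwise the normal approximation with tie
correction; identical constant samples return p = 1 with a warning, and the
exact branch is verified against full enumeration of label assignments.
Normality uses a Lilliefors-style KS test (mean and SD estimated from the
sample) with the p-value from seeded Monte-Carlo simulation of the
location-scale-free null. Size dependence uses Spearman correlation against
the effective diameter √(D_AP·D_Lat) (the choice of "body size" variable is
configurable). No multiple-testing correction is applied.

## Problem sizes

Tests and the acceptance script run a desk-scale configuration chosen as
the package's reference experiment: a 96 × 96 × 32 grid at (4, 5, 6) mm,
48 × 32 localizers, 64 AP output bins, a depth-3 network with 8 base
channels, 200 training and 50 test phantoms, 20 epochs. One study trains in
roughly a minute on one CPU; the reference 144/64/184 matrices and depth-5
network are supported through the same configuration objects.

## What the synthetic data does and does not show

The generator reproduces the geometric structure of the problem — body and
lung bounding boxes, couch and blanket interference, scan-range dependence,
population diameter spread, mis-centering prevalence, and the magnification
physics that couples couch height to the scout image. It does not emulate
CT noise texture, beam hardening or realistic HU values, anatomical shape
beyond ellipsoids (no breasts, arms, or asymmetry), breathing-phase
mismatch, or vendor-specific localizer pixel semantics. Passing tests
therefore demonstrate that the pipeline is geometrically correct and that
the couch-height cue is learnable end-to-end under noiseless conditions;
they do not certify clinical accuracy on patient data, where the
reconstruction task is harder and the segmentation faces real anatomy.

## Known limitations

* The placement head assumes a single global vertical shift per case; a
  patient lying obliquely would need a Z-dependent shift.
* The divergent projector applies one magnification factor at the
  body-center height rather than height-resolved fan-beam ray tracing.
* Blanket removal relies on an air gap between blanket and skin; full
  contact defeats intensity-based separation.
* The Mann–Whitney exact branch is combinatorial and restricted to small
  samples by design; large-sample p-values use the tie-corrected normal
  approximation.
* Per-scanner models are supported through configuration (source ids,
  stratified splits, separate checkpoints) but all shipped experiments use
  a single synthetic scanner.
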