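# Methods

## Problem and model

Yield estimation for grapes from single RGB images is dominated by
occlusion: berries hide behind foliage and behind each other, so any method
that counts only what is visible systematically underestimates the crop —
in heavily occluded field imagery only around a fifth of the berries in a
bunch may be visible at all.  Writing `V` and `O` for the visible and
occluded berry sets of an image, the target quantity is the total count
`C = |V| + |O|` (and the bunch weight in grams).

The pipeline has three stages:

1. **Segmentation** `s: I -> M`.  A U-Net maps the RGB image to a
   two-channel (grape vs background) output; the predicted mask marks
   grape-cluster pixels.
2. **Mask overlay**.  The mask is applied to the image so background pixels
   are suppressed (set to black); the counting stage sees grape evidence
   only.
3. **Count/weight regression with occlusion correction** `r: M -> R`.
   A small convolutional regression network with two scalar heads predicts
   the count and the weight from the masked image.

The occlusion correction is realised twice, deliberately:

* **Implicit (learned).**  The regression targets are the *total* count
  (visible + occluded) and the measured weight.  A network supervised this
  way learns the visible-evidence-to-total mapping directly; nothing at
  inference time requires knowing the true count.  (The alternative reading
  — feeding true count and weight in as input features — cannot yield a
  usable predictor, since the count is the quantity being predicted.)
* **Explicit (closed form).**  `OcclusionRatioCorrector` estimates, per
  stratum (grape colour x foliage level by default), the training mean of
  `total_count / visible_count`.  A visible-count estimate — e.g. the
  distance-transform blob counter `count_visible_blobs` — multiplied by the
  stratum ratio and rounded gives a corrected total.  Strata with fewer
  than `n_min` (default 5) records fall back to the global ratio, as do
  unseen strata (with a warning).  The ratio is >= 1 whenever occlusion is
  non-negative, and the corrected count is monotone in the visible
  estimate.

Count accuracy is reported as MAE and R² (`R² = 1 − SS_res/SS_tot`, SS_tot
taken about the mean of the observed values), segmentation accuracy as
per-pixel IoU, precision, recall and F1 with grape foreground as the
positive class.  `deviation_accuracy` reports `100·(1 − MAE/mean(y))`, one
concrete reading of "accuracy as percentage deviation", and is reported
alongside MAE rather than instead of it.

## Synthetic scene generator

The simulator emulates a controlled indoor imaging design: three grape
clusters per image; blue, green and purple varieties; low/medium/high
foliage tiers; white-wall and blurred-green ("bokeh") backgrounds; four
view angles (0/90/180/270°) of each bunch arrangement sharing one
`group_id`; and three 3:4 resolution tiers.  Geometry is simple on
purpose — berries are disks composited back-to-front over an object-id
buffer, foliage is green ellipses drawn over the bunches — because that
makes the ground truth *exact*: the mask is precisely the set of pixels
whose top-most object is a berry, and a berry is visible iff its top-most
pixel count reaches a threshold (default 5% of its disk area, minimum one
pixel).  Occlusion severity is controlled by two knobs (berry packing
tightness and foliage density); `calibrate_occlusion` bisects a combined
knob until the mean visible fraction matches a target, validating on an
independent probe stream.  The fractional part of the effective foliage
count is rendered as one partially-grown ellipse, so occlusion varies
continuously (and monotonically) with density; the packing component of
the calibration knob is quantized because layout resampling makes it an
inherently jumpy control.

Weight follows a linear per-berry-mass model (default 1.5 g/berry) with
multiplicative Gaussian noise (default sd 5%), truncated at zero.  This is
the simplest law that supports exact parameter-recovery tests.

Berry radius is a property of the variety, not of the bunch count: bunches
with more berries spread wider rather than shrinking their berries, so
total berry area genuinely carries the count signal the regression stage
must learn.  The packing gap is enforced across clusters (at the reference
view angle), so `packing_tightness=0` means globally disjoint disks and
berries are kept fully in frame.  A 48x64 frame fits roughly 5–15 disjoint
berries per cluster; the zero-occlusion fixtures use that range.

View angles are in-plane rotations of each cluster's berry layout, which
preserves the group structure without 3D modelling.  Foliage elements are
drawn from a fixed per-cluster pool of 64 pre-sampled ellipses, so raising
the foliage density only adds occluders and never reshuffles existing ones
— visible counts are monotone non-increasing in density, a property the
tests sweep.

Randomness: one integer master seed; every per-scene seed is derived by a
splitmix64-style counter hash (`derive_seed`), so whole datasets
regenerate byte-identically.

What the generator does **not** emulate: photorealistic texture, specular
highlights, 3D bunch geometry, camera optics beyond the blurred-disk
bokeh, lighting variation, or real annotation noise.  Passing tests
therefore demonstrate that the pipeline mechanics (training, overlay,
correction, evaluation, splitting) are correct and that the studied
phenomena appear under controlled conditions; they do not certify accuracy
on real vineyard imagery.

## Networks and training

No GPU framework is used: both networks run on a small numpy layer core
(`grapeyield._nn`) with explicit forward/backward passes (3x3/1x1 'same'
convolutions via im2col, 2x2 max pooling, 2x2-stride-2 transpose
convolutions, dense layers, ReLU) and Adam.  Gradients are verified against
central finite differences in the test suite.

* **U-Net** (`UNetSegmenter`): depth 4, base 16 channels doubling per
  level, skip connections by concatenation, transpose-convolution
  upsampling, 1x1 head onto two channels.  Cross-entropy loss, Adam with
  learning rate 0.001, batch size 8; inputs reflect-padded to a multiple of
  `2**depth` and cropped back.  Argmax ties resolve to background
  (conservative foreground calls).  No augmentation and no early stopping.
* **Counter** (`CNNYieldRegressor`): three conv blocks (16/32/64 channels,
  each 2x2 average-pooled), a global average pool, dense layers (64, 32),
  two linear heads.  Summed MSE over both heads; targets are standardised
  internally per head and de-standardised at prediction, since raw-scale
  MSE at count ~60 / weight ~90 g magnitudes is poorly conditioned under
  one fixed learning rate.  Average pooling (local and global) is chosen
  deliberately: counting integrates evidence over the image, and
  sum-preserving pooling lets the readout generalise the area-to-count
  rule instead of memorising scene layouts; max pooling and a plain
  flatten are available (`pool="max"`, `global_pool=False`) but generalise
  markedly worse at desk-scale training sizes.

Training is deterministic for a fixed seed in single-threaded execution;
checkpoints are single `.npz` files with a versioned JSON header, and a
save/load round trip reproduces bit-identical predictions.

## Desk-scale defaults

The package's defaults are sized for a single CPU core.  Scenes default to
desk resolution tiers 60x80 / 120x160 / 240x320 (the full 120x160 /
480x640 / 1080x1440 tiers are available via `tier_table="paper"`);
training examples in the tests and the acceptance script use 48x64 inputs,
datasets of roughly 100–150 scenes, U-Nets of depth 3 with 8 base channels
trained 10–20 epochs at learning rate 2e-3, and counters trained 12–15
epochs.  With the full-size recipe (depth 4, base 16, 50 epochs, learning
rate 1e-3, 480x640) the code paths are identical; only sizes change.  The
resolution study resizes one set of reference renderings to tier sizes
24x32 / 36x48 / 48x64, and scores predicted masks against the
reference-resolution ground truth — so lower tiers genuinely lose boundary
information, mirroring how one set of captures is downsampled in practice.

## Experiment harness

`run_ablation` trains the counter twice per condition and seed — on raw
images and on mask-overlaid images — sharing one group-aware split per
seed so the arms differ only in the stage under study.  The overlay masks
come from a trained segmenter when one is passed; with `segmenter=None`
the ground-truth masks stand in as an idealised stage 1, isolating the
stage-3 effect.  `run_segmentation_study` reports IoU/F1 per resolution
tier or per grape colour, and `summarize_report` takes across-seed medians
(invariant to seed order).  `paired_t_test` implements the two-sided
paired t statistic on matched MAE series with `n−1` degrees of freedom and
raises a dedicated error when all differences are equal; it is checked
against an independent reference implementation to 1e-9.

Directional findings the harness reproduces on synthetic data: IoU rises
with resolution tier; green grapes on a green bokeh background segment
worse than blue; and adding the segmentation stage lowers counting MAE in
that low-contrast regime.  Absolute values depend on the rendering
simplicity and the desk-scale sizes and are not comparable to results on
real imagery.

## Numerical conventions and degenerate inputs

* IoU of two empty masks is 1.0; zero-denominator precision/recall/F1
  return 0.0 and emit `DegenerateMetricWarning`.
* R² requires non-constant observations; MAE requires a non-empty series.
* `split_by_group` needs at least two groups; the test-group count is the
  prefix of a seeded group shuffle whose record fraction is closest to the
  requested one.
* Correction-factor fitting excludes records with zero visible count (with
  a warning) and errors out if none remain.
* Empty scenes (zero berries) render an empty mask, zero weight, and are
  legal inputs everywhere downstream.
* `epochs=0` is a valid no-op fit: predictions keep their shape contract.

## Known limitations

* The renderer's simplicity means segmentation can saturate near-perfect
  IoU on easy presets; study presets use the low-contrast background to
  stay off the ceiling.
* The blob counter is exact for non-touching disks and separates merged
  pairs by distance-transform peaks, but under-counts heavily fused
  clumps; it is a baseline feeding the explicit correction, not the
  headline counter.
* The explicit ratio estimator assumes the test-time occlusion regime
  matches training (the ratio is a property of the acquisition setup); a
  shift in foliage density between fit and use biases corrected counts.
* Weight and count share one backbone; with very small training sets the
  heads can trade accuracy against each other.
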