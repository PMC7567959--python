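# Methods

## The problem and the pipeline

Olfactory-bulb (OB) volume on coronal T2-weighted MRI is a robust
correlate of olfactory function but not of its cause: both
Parkinson's-disease-related olfactory dysfunction (PD) and
non-parkinsonian olfactory dysfunction (NPOD; post-viral, sinonasal)
shrink the bulb to a similar degree. The working hypothesis behind this
package is that disease-specific information sits not in the bulb volume
itself but in the bulb's *surroundings* — the cleft between the bulb and
the overlying orbitofrontal cortex and the olfactory sulcus — and that a
convolutional classifier looking at the bulb *neighbourhood* can separate
PD from NPOD where manual volumetry cannot. The pipeline couples five
stages: phantom generation, planimetric volumetry, psychophysics, CNN
classification with Grad-CAM saliency, and group statistics.

## The phantom cohort generator

No clinical scans are distributed, so the generator *is* the study
population. Defaults encode the study conditions the pipeline targets:

| parameter | default | meaning |
|---|---|---|
| n per group | 15 / 15 / 15 | PD / NPOD / control subjects |
| slices per subject | uniform 5–9 | bulb-containing coronal slices (mean ≈ 7) |
| pixel spacing | 0.2 mm | in-plane resolution |
| slice thickness | 2.0 mm | planimetric multiplier |
| raster | 672 × 896 px | full slice, exercised by the 150 px crop path |
| bulb volume means | 55 / 37 / 37 mm³ | control / PD / NPOD, per side |
| bulb volume SD | 8 mm³ | between-subject, per side |
| surround_effect | 1.0 | PD-vs-NPOD structural difference ∈ [0, 1] |
| noise SD | 6 intensity units | additive Gaussian on 8-bit intensities |

Bulb volume means are not taken from any printed table (the clinical
report shows them only graphically); 55 mm³ for controls with a ~33%
reduction in both patient groups and no PD–NPOD difference is a
representative choice from the OB-volumetry literature and matches the
null PD-vs-NPOD volumetric finding the pipeline is designed around.

**Slice geometry.** Each bulb-containing slice renders two bright
ellipses (left/right bulb) on a dark background beneath a bright cortical
band. Per-slice cross-sectional areas follow a bell-shaped
anterior→posterior profile with an abrupt posterior drop (the bulb
narrowing into the olfactory tract); semi-axes are chosen so that the
*polygon* areas of the 48-vertex ground-truth contours, summed and
multiplied by slice thickness, equal the subject's drawn true volume
exactly. One empty slice precedes and follows the bulb-bearing block so
the slice-inclusion rule is testable.

**The planted surround signal.** For PD subjects (only), the bulb–cortex
gap widens from 0.6 mm to 0.6 + 2.0·`surround_effect` mm and the sulcus
notch carved into the cortex shallows from 3.0 mm to
3.0 − 2.0·`surround_effect` mm, with small per-subject jitter. At
`surround_effect = 0` the three groups are structurally identical above
the bulb — the negative-control condition. The phantom is deliberately
schematic: no Rician noise, no bias fields, no anatomy beyond the
bulb/gap/sulcus/cortex motif, no partial-volume effects. Passing controls
therefore demonstrate that the *pipeline* recovers a planted signal and
refuses an absent one; they say nothing about classification accuracy on
real scans.

**Behavioral truth.** Each subject draws a latent threshold (on the
1–16 staircase scale), and per-trial success probabilities for the two
16-trial subtests, from group-calibrated normal distributions (controls
≈ 10.4 / 12.6⁄16 / 13.5⁄16; PD ≈ 2.2 / 8.5⁄16 / 7.5⁄16; NPOD ≈ 3.0 /
7.2⁄16 / 7.5⁄16), giving expected composite scores ≈ 36.5 (normosmic)
for controls and ≈ 17–18 (hyposmic) for both patient groups. The lapse
rate defaults to 0.02.

**Determinism.** One config seed drives a `SeedSequence` tree with one
child per subject; identical configs give byte-identical cohorts,
including serialized PNG/JSON/CSV output.

## Volumetry

Contour area is the shoelace formula on the polygon vertices in pixel
coordinates times spacing²; shapely's simplicity test rejects
self-intersecting polygons, and a rasterization-based pixel count serves
as an independent oracle in the tests only. Volume is thickness × Σ area
over the inclusive first-to-last visible-slice window. In the
measurement combiner, a difference of *exactly* 10% of the average counts
as agreement (the rule's prose leaves equality unassigned; agreement
avoids unnecessary third measurements), and a third measurement exactly
equidistant from the first two averages all three — both choices are
deterministic and documented here.

## Psychophysics

The staircase is 2-down-1-up on an abstract 1–16 sensitivity scale with
*higher = detects more dilute*: one error steps −1 (toward
concentration), two consecutive correct responses step +1. A direction
change records a reversal at the turning-point value; a step blocked by
the scale boundary neither moves nor reverses; the run starts at scale 1
(configurable) and terminates at 7 reversals, scored as the mean of the
last 4, or at `max_trials` (default 200) unscored. The responder model is
P(correct) = 1/3 + 2/3·(1 − lapse)·σ((t − scale)/spread) with spread 0.5
by default — a 3-alternative forced choice with chance floor 1/3.
Whether the very first step direction can count toward a reversal is a
convention; here the first step only establishes the direction.
Discrimination and identification are 16 independent Bernoulli trials
each; the odor-specific structure of the real tests is not modeled.

## Image preparation

Crops are 150 × 150 px centred on the per-scan bulb anchor (midpoint of
the two bulb centroids, from contours); windows overrunning a border are
shifted inward, never padded. Augmentation samples rotation uniformly in
[−5°, +5°], row/column shifts in ±5% of each dimension, shear angle in
[−0.05, +0.05] rad (the "shear intensity" convention of the common
augmentation tools is an angle), a horizontal flip with probability 0.5,
and divides intensities by 255; resampling is bilinear with nearest-edge
fill so no zero-intensity border artifacts appear next to the bulb.
Splitting is by subject, stratified by group with largest-remainder
rounding of the 3:1:1 ratios, and augmentation is applied *after*
splitting and only to the training partition — augmented copies can
therefore never leak across partitions.

## Classifier

The architecture is fixed (see README). Channels default to 3 — the
choice that yields the 5,318,946-parameter reference count — with
grayscale crops replicated across channels; a single-channel variant
would have 5,318,370 parameters. Hidden activations are rectified linear
(also required by Grad-CAM's nonnegativity convention), the head is a
2-unit softmax with categorical cross-entropy, dropout (0.5 after each
pool stage and after the dense layer) is active only during training and
does not count toward the 7-layer enumeration. Weights are He-normal
initialised from the model seed; the training seed fixes batch order and
dropout masks, making runs bit-reproducible. No early stopping, learning
rate schedule, or class weighting.

The implementation is self-contained numpy: im2col convolutions via
`sliding_window_view`, exact argmax routing in the max-pool backward pass
(ties route to the first maximal element), explicit backprop and plain
SGD with optional momentum. This keeps the full gradient path available
to Grad-CAM and makes small-image training fast on one CPU.

**Scaled-down control protocol.** Clinical-scale training (100 epochs,
~5000 augmented 150 px scans) is not meaningful on phantoms and not
needed for validity. The control experiments in
`olfbulb.experiments` use 12 + 12 patients, 150 px crops downsampled to
40 × 40, 3 augmented copies per training scan, 15 epochs at learning
rate 0.02 (the 3 × 10⁻⁴ reference rate pairs with the 100-epoch,
5000-scan budget and barely moves at this scale; batch size 32 and the
architecture are unchanged). A run takes ~20 s; the positive control
(surround_effect 1) reaches held-out accuracy ≈ 1.0 and the negative
control (surround_effect 0) stays at chance.

## Saliency

Grad-CAM uses the gradient of the *logit* (pre-softmax score) of the
target class with respect to the post-ReLU activations of the second
convolution layer; channel weights are the spatial means of that
gradient, the map is the rectified weighted channel sum, upsampled
bilinearly to input size and normalised to max 1 (an all-negative
weighted sum yields a valid all-zero map). Group maps translate each
scan's map by the integer offset taking its bulb anchor to the rounded
mean anchor, average over the covered pixels, and threshold at the 80th
percentile of the covered mean (configurable). Averaging is provided per
class or pooled; the shipped pipeline pools both classes. Finite
differences validate the gradient path in the tests at points where the
max-pool is locally smooth; at ReLU-zero ties inside a pooling window
the function is non-differentiable and finite differences are undefined
by construction, not a defect.

## Statistics

The mixed ANOVA implements the balanced-design sums-of-squares
decomposition directly (group tested against subjects-within-groups;
side and interaction against the within-subject error; for 3 × 15
subjects and 2 sides the dfs are (2, 42), (1, 42), (2, 42)). With a
two-level within factor sphericity holds trivially and no correction is
applied. Unbalanced designs raise an error instead of being silently
approximated; `pingouin.mixed_anova` is used as an independent oracle in
the tests. Pearson p-values come from the t transform with n − 2 df;
Bonferroni multiplies by an explicit, user-chosen comparison count m
(the appropriate comparison family is analysis-specific).

## Numerical and degenerate-input choices

- Max-pool gradient ties route to the first maximal element; with
  continuous noise ties occur only at ReLU zeros, where any subgradient
  is valid.
- Odd feature-map dimensions are floor-cropped before pooling (standard
  valid-pool arithmetic); the parameter-count closed form uses the same
  arithmetic and is property-tested against layer enumeration across
  input sizes.
- Metric ratios with zero denominators are reported as explicitly
  undefined, never coerced to 0.
- All stochastic entry points accept either an integer seed or a
  `numpy.random.Generator`; cohort generation spawns independent child
  streams per subject so cohorts are reproducible under subject-count
  changes of downstream code.

## Known limitations

- The phantom's appearance is schematic; no claim is made that classifier
  accuracy or saliency geometry transfers to clinical scans.
- Volumetric recovery from *ground-truth* contours is exact by
  construction; the package does not model human contouring error beyond
  the measurement-combiner protocol, and does not segment bulbs from
  images.
- Training determinism holds for this numpy implementation; it is a
  contract of the implementation, not of floating-point reordering across
  BLAS backends.
- Scan-level metrics treat scans as independent, as is conventional for
  this design; the optional subject-level majority vote is provided as an
  extension.
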