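# Methods

## Problem and approach

ChronoMID classifies longitudinal stacks of 2-D cross-sectional images —
the motivating case is weekly μCT scans of mouse tibiae under an anabolic
(PTH) treatment versus healthy controls — by combining spatial and temporal
information. Time enters the models in two forms:

* **explicit timestamps**: the raw integer week since study start, fed as a
  unit-sized input next to the flattened convolutional features (never
  normalised, so irregular and open-ended studies remain representable);
* **implicit difference maps**: the pixel-wise subtraction
  `D[i,j] = I_t[i,j] − I_t0[i,j]` between a *comparison* image at week `t`
  and an aligned *reference* image at an earlier week `t0`. *Absolute*
  differencing takes the subject's first recorded week as the reference and
  captures long-range monotonic change; *relative* differencing takes the
  most recent earlier week and captures short-range change. A subject's
  earliest week has no reference and receives a uniform map filled with the
  minimum intensity of its own comparison image (per image, not a global
  constant, so early-week maps retain inter-image variation and stay
  consistent with the expansion padding).

Cross-modal CNNs (X-CNNs) process image and difference map in separate
convolutional streams that exchange feature maps after every chain through
1×1 convolutions (8 filters, both directions, merged by concatenation).

## Preprocessing pipeline

1. **Expansion.** All images are expanded to the dataset-maximum height and
   width, centred, with padding set to the per-image minimum intensity.
   When the leftover margin is odd, the extra row/column goes to the
   bottom/right — an arbitrary but fixed tie-break chosen so expansion is
   bit-reproducible. No pixel normalisation or resampling is applied
   anywhere in preprocessing.
2. **Registration.** Reference/comparison pairs are aligned by the integer
   translation `(dy, dx)` of the reference that maximises the cross-
   correlation with the comparison, computed on min-subtracted images via
   FFT. Restricting to integer translations keeps the subsequent
   subtraction exact and lets tests verify recovery against an exhaustive
   shift search. Score ties (e.g. constant images) resolve to the smallest
   `|dy|+|dx|`, then lexicographically. Vacated pixels after the shift take
   the per-image minimum, mirroring the expansion fill. Rotational, affine
   and deformable registration are out of scope: the upstream multi-week
   rigid registration is treated as already performed, with small residual
   translations the only misalignment modelled.
3. **Pairing.** Weeks of the same subject have different slice counts, so
   the k-th reference slice is paired with the k-th comparison slice (scans
   start at the same anatomical landmark), stopping when either week is
   exhausted; surplus slices are reported as unused.
4. **Differencing.** Signed integer subtraction, stored as `int32`
   (differences of 16-bit images need 17 bits); values are never clipped or
   rescaled. The comparison image and its difference map therefore share a
   frame of reference.

Preprocessing runs once and persists to `samples.npz` + `pairs.csv`.

## Partitioning

The data regime is deep-not-wide: thousands of images from few subjects,
with adjacent slices nearly identical. The test set is therefore selected
at **mouse-week** granularity: `round_half_up(0.2 · #mouse-weeks)` whole
mouse-weeks are held out, and every slice of a held-out mouse-week is in
test and only test. The remaining images are randomly permuted and split
90/10 into train/validation at image level (the permutation wording of the
protocol; train↔val slice correlation is accepted since only the test set
supports claims). Difference-map samples inherit the split of their
comparison image's mouse-week, as the comparison week carries the
label-relevant time point. Mouse-level holdout is deliberately *not* used:
the protocol being reproduced partitions by mouse-week, which permits
subject-level appearance memorisation — see "What the synthetic experiment
shows" below.

## Architectures

All six variants share: 3×3 same-padding convolutions, ReLU activations,
He-Gaussian initialisation, 2×2/stride-2 max pooling (floor division),
batch normalisation after pooling, dropout 0.25 in chains 1–4 (none in
chain 5), five chains total, then dense layers of 64 and 32 units with
batch normalisation only (BN and dropout conflict in dense layers), and a
softmax output over the classes. L2 (λ = 3·10⁻⁴) applies to conv and dense
kernels, not biases or BN parameters. Filter plans: single-stream variants
use 16/32/32/32/32 filters per chain; cross-modal streams use half
(8/16/16/16) except the final chain (32). Cross-connections default to
after the BN/dropout block; the alternative placement (before
regularisation) is architecturally open and exposed as a flag.

Parameter counts include BN moving statistics (4 per feature, two
trainable). At the full 501×763 input the baseline CNN counts 781,586
parameters (< 900 K) and the X-CNN variants 1,837,346–1,837,410 (> 1.5 M),
consistent with the published bounds for these architectures. Exact
published per-model totals are not reconstructible from the published layer
tables under standard conventions and are deliberately not targeted.

The training loop is plain mini-batch optimisation with Adam (the
optimiser is unspecified in the protocol and is config-exposed; the
package defaults to step size 3·10⁻³ with global gradient-norm clipping at
5.0, chosen because the desk-scale datasets yield only ~100 optimizer
steps in five epochs and an occasional large early step otherwise
destabilises batch normalisation), batch size 32, categorical
cross-entropy, a fixed epoch budget (5 or 10, no early stopping), and
seeded shuffling/initialisation/dropout so identical seeds give identical
weights. The layers and
backpropagation are implemented in NumPy (im2col convolutions backed by
BLAS matrix products); every layer's backward pass is validated against
central finite differences of a smooth surrogate loss in the test suite.
Raw pixels are divided by the fixed full-scale constant 65535 at the model
input — a constant affine rescale for the numerical stability of
He-initialised weights, not a data-dependent normalisation.

Evaluation is image-level: each comparison slice (plus difference map) is
one sample. PTH is the positive class; accuracy is
`(TP+TN)/(TP+TN+FP+FN)`, appropriate for the near-balanced splits.
Prediction ties break toward class index 0 for determinism. Accuracies
across repeated runs are macro-averaged with the sample standard deviation.

## Synthetic phantom generator

The generator emulates the structure of the real study without its 20 GiB
payload: per group (wild/PTH) `n` mice, weeks 0–8 with week 2 missing for
all mice, 6–10 slices per mouse-week, image heights/widths drawn per
mouse-week from 48–64 px (a scaled-down stand-in for the real 400–800 px
crops), and a per-mouse-week random integer translation of up to ±3 px
(residual registration error).

Each slice is a soft-edged annulus (cortical ring) on a dark background.
All random draws are label-blind and keyed to the mouse's *position* in its
group, so `wild_i` and `PTH_i` are statistical twins: with trend, noise and
jitter all zero they render bit-identically, and their week-0 distributions
are identical at any setting. The only label-dependent term is the trend:
PTH ring intensity at week `w` is `base + trend_per_week · w` (default
2500/week); wild stays at `base`. Per-pixel Gaussian noise (σ = 1000) is
added and values are clipped to the 16-bit range.

Design choices that shape what each model *can* learn:

* **Ring geometry is shared, not subject-specific** (radius 15 px,
  thickness 4.5 px, mouse-independent axial taper along the slice index):
  single images carry no subject-identity cues in shape, so the baseline
  CNN cannot classify by recognising individual animals.
* **Baseline intensities lie on the trend lattice**: each mouse's `base` is
  drawn from U{10000, 10000+2500, …, 55000} — multiples of the weekly
  trend. A treated ring after `w` weeks is then exactly as bright as some
  other animal's baseline, making single-image intensity ambiguous by
  construction rather than by sampling luck.
* **An axial sensitivity profile** multiplies each slice position's whole
  trajectory by a fixed factor U(0.8, 1.2), constant across weeks (a
  scanner property of the axial position). It cancels between paired
  reference/comparison slices up to a benign scale on the difference
  signal, but smears single-image intensity levels across several lattice
  spacings, defeating intensity→label lookup for the baseline.
* `trend_per_week = 2500`, `noise_sd = 1000`: the week-1 absolute
  difference map has per-pixel SNR ≈ 1.4–2 over a ~400-pixel ring —
  trivially detectable after spatial aggregation — while eight weeks of
  accumulated trend (20000) stay well inside the baseline spread (45000).
  The effect size has no published value; it is a free parameter chosen so
  that the differencing signal separates the classes at this scale.
* integer-valued jitter: registration recovery is testable exactly.

Counter-based seeding (`(seed, position, week, slice, stream)`) makes every
slice independently reproducible; identical configs give identical bytes.

What the generator does **not** emulate: real cortical/trabecular
microstructure, localised remodelling (the resorption/OVX phenotype is out
of scope), rotational misalignment, growth-related shape change, scanner
artefacts. Passing tests therefore show that the pipeline and models behave
as specified on data with the assumed statistical structure, not that the
classifier performance transfers to real μCT data.

## What the synthetic experiment shows — and a structural caveat

With the class signal confined to the temporal trend, single images carry
no class information, so the baseline CNN can beat chance only through
subject-appearance memorisation (mouse-week partitioning leaves the same
subject's other weeks in training) — a slow, fine-grained lookup that
five epochs of training do not reliably achieve. The absolute-differencing
X-CNN, in contrast, receives the trend directly as the mean level of the
difference map and separates the classes almost immediately. This
reproduces the published ordering (absolute differencing ≫ baseline).

One structural limit is worth stating plainly: samples from a subject's
*earliest* week consist of a uniform initial-fill map plus a week-0 image
whose distribution is class-identical, and the generator's label-blind
anatomy makes a PTH mouse's week-0 stack statistically indistinguishable
from its wild twin's. Week-0 samples average about 15% of the test set
(1/8 of mouse-weeks, slightly inflated because absolute-mode pairing caps
every later week's sample count at the week-0 slice count), and no
classifier can average better than 50% on them, so the expected ceiling
for test accuracy on this synthetic design is about 92–93% rather than
100%, with substantial seed-to-seed variation from which mouse-weeks land
in test (observed 86–95% over repeated studies). In practice the trained
networks resolve every week-1+ test sample and predict the control class
on week-0-like inputs — the calibrated response, since a week-0 stack
matches the training appearance of its wild twin. (On the real data the
published perfect accuracy implies the corresponding early-week samples —
PTH begins only at week 4 — were resolved by subject-level appearance
cues, which the mouse-week unit permits; the label-blind generator
deliberately does not manufacture such cues.)

## Numerical and degenerate-input conventions

* Registration tie-breaks and prediction tie-breaks are fixed (see above).
* Pooling an odd dimension drops the trailing row/column (floor), matching
  the parameter-count oracle.
* BatchNorm: ε = 10⁻⁵, moving-average momentum 0.9; evaluation uses moving
  statistics.
* A single run reports a standard deviation of 0.0 (no dispersion
  observable from one run).
* Empty index, empty split, missing weeks, non-integer weeks, RGB inputs,
  images larger than the canvas, and shifts beyond the canvas all raise
  typed errors rather than degrading silently.

## Problem sizes used in the bundled experiments

The bundled reproduction uses 8 mice per group, weeks 0–8 without week 2,
6–10 slices per mouse-week and a 64×64 canvas (~1000 images, ~128
mouse-weeks), trained for 5 epochs — the package's chosen desk-scale study
conditions. Full-size (501×763) builds are exercised for construction and
parameter counting; training at that scale is a matter of compute, not
code.
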