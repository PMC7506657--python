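# Methods

## Data model

A *step segment* is one labeled gait step: six synchronized series —
triaxial acceleration in g and triaxial angular velocity in deg/s — at a
common sampling rate (100 Hz default), at least 4 samples long.  Steps may
vary in length; nothing downstream assumes equal lengths.  Labels are the
five gait activities with fixed integer codes 0–4 (down incline, up
incline, level, down stairs, up stairs).  Datasets are long-format CSV
(one row per sample, grouped by a step-id column); label text is matched
case-insensitively against an alias table so third-party exports ingest
without edits.  Only a single (torso-worn) sensor stream is modeled;
multi-sensor fusion is out of scope.  Segments flagged `real` get a soft
range check against the ±4 g / ±500 deg/s hardware ranges (warn, never
reject); `synthetic` and `augmented` provenance skip it.

## Preprocessing

All six axes are low-pass filtered and smoothed before anything else.

* **Filter**: 4th-order Butterworth, default cutoff 10 Hz at 100 Hz
  sampling — gait energy is concentrated well below 10 Hz.  It is applied
  forward-backward for zero phase, so peak positions (used by the
  width/height descriptors) are not shifted.  Initial conditions follow
  Gustafsson's method, which minimizes edge transients; this matters on
  segments only 40–80 samples long, where reflection padding leaks
  spurious low-frequency energy into the passband.
* **Smoothing**: a normalized discrete Gaussian kernel ("pseudo-Gaussian"),
  σ = width/4, truncated at ±width/2, reflective boundaries, default width
  5 samples; width 1 is the identity.
* **Forward-direction (FD) selection**: per step and per sensor, the axis
  with maximal *mean-removed* power (mean squared deviation from the
  series mean).  Mean removal is essential: the gravity-aligned
  accelerometer axis carries a ~1 g DC offset that would otherwise always
  win regardless of movement content.  Ties break to the lowest axis
  index.  FD is chosen independently for the accelerometer and gyroscope.
* **Magnitude vector (XYZ)**: per-sample Euclidean norm of the filtered
  and smoothed triad; non-negative and invariant to device rotation.

## Augmentation operators and treatments

Every operator draws variation factors from N(μ=1, σ=0.2); non-positive
draws (probability ≈ 3·10⁻⁷) are redrawn.  Magnitude-modifying (DMM)
operators preserve length; length-modifying (DMF) operators preserve
per-sample values and share one draw across all six axes:

* *scaling* — one factor per signal multiplies every sample;
* *jittering* — an independent factor per sample (multiplicative noise;
  read literally from "multiply a random value to each element", and
  isolated behind one function so additive jitter could be swapped in);
* *smoothing* — normalized Hann-window moving average, window length
  round((L/10)·f) clipped to [1, L]; windows shorter than 3 samples
  degenerate to the identity because the Hann taper vanishes at its
  endpoints;
* *downsampling* — retained length L′ = round(L/f) with f redrawn until
  f > 1, indices evenly spaced from a random start offset, the same index
  set applied to all six axes;
* *cutting* — n = round((L/10)·f) frames removed from the edges, ⌈n/2⌉
  from the start and ⌊n/2⌋ from the end (the start takes the extra frame
  for determinism), same block kept on all axes; draws that would leave
  fewer than 4 samples are redrawn.

The **balancer** raises every class to the majority count, cycling
round-robin through the five operators and drawing each source step
uniformly with replacement from the class's *original* instances —
synthetic steps never seed further synthesis, which prevents drift.  The
**subsampler** draws each class down to the minority count without
replacement.  Both are deterministic under a fixed generator.  Applied to
the published composition (2098/1890/9865/882/956), the three treatments
yield totals 15,691 / 4,410 / 49,325 with per-class synthetic requirements
7767/7975/0/8983/8909 — these are exact arithmetic identities the test
suite checks end to end.

Treatments act on raw segments, upstream of both pipelines.  Augmentation
precedes cross-validation splitting by default (matching the protocol the
stack reproduces); since synthetic steps can then share a source with a
training fold, a `split_before_augment` flag provides the leakage-free
order (treatment applied per training partition only, originals tested).

## Shallow pipeline

Five descriptors per selected (sensor, signal): segment **width**
(duration in samples, counted once per step), **height** (max − min),
**mean**, **SD**, and **power** (mean of squared values, deliberately not
mean-removed: as a feature it describes the signal including its offset,
unlike FD selection).  Dimensionality is 4·|sensors|·|signals| + 1 —
5, 9 or 17 over the nine configurations.

Classifiers: Gaussian Naive Bayes; an entropy-criterion decision tree
standing in for C4.5 (exact C4.5 pruning is out of scope — the tree
variant is not what is under study); RBF SVM (C = 1, γ = scale); k-NN
(k = 5).  Features are z-scored inside each training fold to avoid
leakage.  Evaluation is stratified five-fold cross-validation with
predictions aggregated over all five test folds; any class with fewer
than five instances is a hard error naming the class.

## GAF imaging

Rescale x̃ᵢ = ((xᵢ − max X) + (xᵢ − min X)) / (max X − min X) maps the
maximum to 1 and the minimum to −1; a constant series maps to all zeros
(neutral angle π/2) since the formula is otherwise undefined.  Angles
φ = arccos(x̃) (argument clipped to [−1, 1] against floating-point
overshoot); radii rᵢ = tᵢ/N are computed for polar plotting but do not
enter the Gramian.  The summation form G = cos(φᵢ + φⱼ) is implemented
(the difference form is out of scope); its diagonal equals 2x̃² − 1.
Because rescaling removes offset and scale, the encoding is invariant to
positive affine transforms of the signal.

Rescaling is per step (the formula is written over one series); signals
are first resampled to the image side — piecewise aggregate approximation
(bin means) when shrinking, linear interpolation when stretching — then
quantized linearly from [−1, 1] to 0–255.  Default side 64 (steps at
100 Hz are ~40–120 samples; 64 balances fidelity against CNN cost); the
desk-scale experiments use 32.  Channel map: R = AccXYZ, G = GyrXYZ,
B = AccFD.

## CNN

Five 3×3 same-padded convolutions with channels (16, 32, 32, 64, 64),
ReLU after each, 2×2 max-pooling after convolutions 1, 3 and 5, then
FC 128 → FC 5; He initialization; softmax cross-entropy; Adam at 1e-3,
batch 32.  These widths are the smallest conventional instantiation of
the fixed 5-conv/3-pool/2-FC census; the image side must be divisible
by 8.  The network is implemented directly in numpy (float32, im2col
convolutions, analytic backprop verified against central differences), so
training is bit-for-bit reproducible under a fixed seed and runs on one
CPU.  Inputs are scaled to [0, 1].  Epoch training loss is the
sample-weighted mean over batches, so it is independent of the batch
partition (a zero learning rate yields an exactly constant trace).  A 10%
holdout of the training partition supplies the validation-loss curve.
Train/test splitting is stratified by default (per-class 80%, rounded); a
non-stratified variant exists behind a flag because both policies occur
in practice.  Non-finite losses abort with diagnostics.

## Evaluation

Per-class precision, recall and F-measure (harmonic mean 2PR/(P+R), 0
when P + R = 0) with supports; accuracy; macro (unweighted) and
support-weighted averages; and the *population* standard deviation of the
five per-class F-measures as the spread statistic printed alongside
weighted averages — the population form is what reproduces the published
spread values (e.g. σ = 0.078 for F = {0.714, 0.748, 0.800, 0.872,
0.925}).  Zero denominators yield 0 and are flagged in the report.
Confusion matrices are counts by (true, predicted); the normalized form
divides each row by its sum (zero-support rows stay zero).  The
attractor/repeller statistic is the column sum of the row-normalized
matrix minus 1: positive values mark classes receiving more predictions
than their expected share.  Metric computation is delegated to
scikit-learn behind this schema; tests pin it to hand-frozen arithmetic.

## Synthetic gait generator

Each axis is a deterministic structure plus white Gaussian noise: a
fundamental sinusoid at the step frequency (~1.9 Hz) with one harmonic, a
~1 g DC offset on the gravity-aligned accelerometer axis, and a
class-signed half-sine pitch pattern on the gyroscope.  Class-conditional
parameters are offsets from the level-walking baseline multiplied by one
`separation` knob: stairs differ strongly in vertical amplitude and
duration, inclines sit close to level (they are the hard classes), and
up/down variants differ in the *sign* of the pitch pattern.  Step
durations are drawn from 0.4–0.8 s; per-class counts follow
largest-remainder apportionment of the proportions (default
13/12/63/6/6 %).  The forward axis is randomized per synthetic subject
via an axis permutation, so FD selection is genuinely exercised.

Two layers of variability make the regimes meaningful.  Sample-level
noise (0.05 g, 8 deg/s) sets the floor; *between-step* variability of the
discriminative parameters (SDs 0.08 g vertical amplitude, 0.05 g forward
amplitude, 0.12 Hz frequency, 45 deg/s pitch), class-independent and
comparable to the unit-separation offsets, makes classes genuinely
overlap at moderate separation.  Consequences, all checked by tests:
separation 0 with zero noise gives chance-level accuracy (~0.2); moderate
separation (1.0) with the default imbalance reproduces the
majority-dominance pattern (majority F ≈ 0.84 vs mean minority F ≈ 0.49,
inclines worst) and augmentation cuts the per-class F spread by half or
more; strong separation (4.0) is near-separable (shallow SVM ≥ 0.95,
CNN macro F ≥ 0.90 at desk scale).

What the generator does **not** emulate: real biomechanics (impact
transients, asymmetry, intra-subject correlation beyond the axis
permutation), age/gender effects, sensor drift or orientation error
within a step, and real inter-class structure beyond the
amplitude/duration/pitch-sign axes built in.  Passing tests therefore
demonstrate that the pipelines behave correctly and reproduce the
*qualitative* imbalance phenomena — not that their absolute accuracies
transfer to any real dataset.

## Problem sizes and numerics

The test suite and the reproduction script run at desk scale by design:
treatment arithmetic at the full published composition (15,691 steps,
augmented to 49,325); shallow patterns at 1,000 steps; the CNN at 32×32,
10 epochs, 200 images per class; chance-level Monte-Carlo checks at 600
steps (large enough that the accuracy estimate is stable to ±0.05).
Numerical conventions collected here: Hann windows below length 3 act as
identity; cut asymmetry favors the start; FD ties break low; constant
series rescale to 0 in the GAF path; arccos arguments are clipped;
quantization maps {−1, 0, 1} to {0, 128, 255} with round-trip error
≤ 1/255.

## Known limitations

* The shallow feature set is time-domain only (no spectral features), by
  scope.
* The numpy CNN targets small images and desk-scale datasets; it has no
  GPU path, no regularization beyond early architecture choices, and
  full-scale training (tens of thousands of 64×64 images, 30 epochs) is
  slow on one CPU.
* The augment-then-split default can leak augmented copies of a test
  step's source into training folds; the flagged alternative removes
  this but changes the protocol.
* Step segmentation itself is out of scope — inputs must already be
  segmented into steps.
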