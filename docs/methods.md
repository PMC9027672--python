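# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
phantoms do and do not establish.

## Phantom generator

Each phantom is a three-mode piecewise-constant image: background, an
elliptical organ, and (for positive cases) a filled circular tumor blob
inside the organ, with per-mode additive Gaussian noise rounded and
clipped to [0, L−1]. Defaults: 128×128 pixels, L = 256 gray levels, mode
means (40, 120, 200), noise SD 6 per mode for generated datasets, organ
semi-axes (42, 30) px, tumor radius 9 ± 3 px. Dataset generation jitters
mode means (±10), organ center (±6 px), semi-axes (±6 px), angle
(±0.35 rad) and tumor radius per item, and re-clips geometry so every spec
stays valid. Labels are balanced by construction and every item derives
from a per-item seed, so generation is a pure function of (seed,
parameters).

These sizes were chosen as desk-scale stand-ins for single-slice CT
crops: large enough that the three intensity modes dominate the
histogram, small enough that a full 200-image pipeline run takes tens of
seconds. What the phantoms deliberately lack: anatomy (no surrounding
organs or bone), partial-volume effects, CT reconstruction artifacts and
streaks, intensity inhomogeneity, and tumors with irregular margins or
contrast close to the organ. Passing tests therefore demonstrate that the
pipeline machinery is correct and recovers planted structure — not that
it would reach comparable numbers on clinical CT, where class contrast is
far weaker.

## Gabor preprocessing

The kernel is a cosine carrier under a Gaussian envelope, parameterized by
wavelength (px/cycle), orientation, envelope sigma (default
0.56·wavelength, about one octave), aspect ratio, phase, and an odd
kernel size (default covering ±3σ). The default bank is one wavelength
(8 px) at four orientations {0, π/4, π/2, 3π/4} combined by maximum
response magnitude — a standard texture-enhancement bank; the source
method names no parameters, so all of this is configuration. Filtering is
spatial convolution with reflect padding (so a centered impulse returns
the kernel exactly, and small phantoms avoid edge ringing), followed by
min–max re-quantization to [0, L−1] so downstream histogramming is well
defined. A constant response maps to all zeros rather than dividing by
zero.

## Multilevel Otsu

Class ranges are closed–open on integer levels, [t_u, t_{u+1}), with
t₀ = 0 and t_{K+1} = L. The objective is the between-class variance
against the **global** mean; empty classes contribute zero rather than
raising, because a swarm proposes degenerate thresholds mid-search and
the objective must remain total. The exhaustive oracle enumerates all
C(L−1, K) tuples with prefix sums (O(K) per tuple), refuses enumerations
above 10⁷, and breaks ties toward the lexicographically smallest tuple so
results are deterministic. Continuous search vectors decode to thresholds
by sort → round → clip to [1, L−1] → push collisions up (and down from
the top if the upper bound is hit).

## Emperor penguin optimizer

Minimization over a box; positions are clamped after every update. Per
iteration C ∈ [1, Itermax]:

- θ = 0 if R > 0.5 else 1 (one uniform draw per iteration);
- θ′ = θ − Itermax/(C − Itermax), implemented literally and capped at
  θ_max = 50 to sidestep the pole at C = Itermax;
- per member, per dimension: U = M·(θ′ + |X_best − X|)·Rand() − θ′ with
  M = 2, V = Rand(), S(x) = (f·e^(−x/l) − e^(−x))² at x = |U| with f = 2,
  l = 1.5, D = |S(U)·X_best − V·X|, and the move X ← X_best − U·D.

The printed source of this recurrence is typographically damaged in two
places (the social-force exponentials and the parenthesization of U); we
use the canonical forms above, under which the search contracts onto the
best agent: on the 5-D sphere (N = 30, 500 iterations) the median best
over 10 seeds is ≈10⁻¹¹⁶, and a 1-D quadratic optimum is recovered to
~10⁻⁶. With the mis-parenthesized U = M·θ′ + |ΔX|·Rand() − θ′ the factor
U is bounded below by θ′ ≥ 1, every move is one-sided, and the search
measurably stalls (median ≈8.5 on the same sphere benchmark), which is
why that literal reading was rejected.

Draw order is fixed (iteration draw, then member-major/dimension-minor
matrices), so runs are bit-reproducible given the seed.

## Multileader optimizer

Per iteration the population is sorted ascending by fitness; the first nL
members are leaders. Normalized fitness (fitᵢ − max)/Σ(fitⱼ − max) gives
the worst member 0; leader probabilities renormalize over the leaders and
accumulate into roulette bands. All-equal fitness (or all leaders tied at
the maximum) makes the normalization 0/0; we take the uniform limit
rather than erroring. Each member then, per dimension, draws a selection
uniform and a step uniform, picks the leader whose band contains the
selection draw, and proposes χ + rand·(Λ − 2χ); the whole-vector proposal
is accepted only if fitness does not worsen. A second, local phase
proposes χ + 2(1 − t/T)·(−0.2 + 0.4·rand)·χ under the same greedy rule;
the multiplier is zero at t = T, and because the move is proportional to
χ itself a coordinate exactly at 0 never moves in this phase — kept as
specified, and harmless under uniform box initialization where exact
zeros have measure zero. Greedy acceptance makes each member's fitness,
hence the population mean and best, non-increasing; the tests assert
this.

## Feature extraction

The default descriptor is per-segmentation-class statistics — area
fraction, mean intensity, intensity SD, Shannon entropy (bits) of the
class's gray-level histogram; zeros for empty classes so the dimension is
fixed at 4·(K+1) + 4 — plus whole-image mean, SD, skewness and excess
kurtosis (the latter two reported as 0 for constant images, where they
are undefined). The MobileNetV2 adapter (grayscale replicated to 3
channels, bilinear resize to 224×224, penultimate global-pooled
activations, 1280-wide) is optional: it requires torch/torchvision and an
explicit local weights path and raises a documented error otherwise —
weights are never downloaded, and the texture descriptor is the default
in all tests and pipelines.

## Autoencoder classifier

One autoencoder per class with sigmoid activations by default and latent
size ⌈m/4⌉ (a compression, as the model requires n < m); features are
min–max scaled to [0, 1] from the training portion only, matching the
sigmoid decoder's range. Classification is argmin of the squared
reconstruction error across the two class autoencoders, ties to label 0.
Both autoencoders' flattened parameters form one MLO decision vector
searched in [−3, 3] per coordinate (sigmoid pre-activations saturate
beyond that; configurable). The fitness is the training error-rate
percentage plus 10⁻³ times the mean own-class reconstruction error — a
pure step-function error rate stalls population search on plateaus, and
the secondary term orders equally-accurate candidates without ever
outweighing a single misclassification at realistic scales. An optional
warm start pretrains each class autoencoder with a few hundred full-batch
gradient steps on reconstruction MSE and seeds one swarm member; it is
off by default and training remains bit-reproducible either way.

A capacity note measured on the shuffled-label control (200 samples, 8-D,
10 seeds): the tuned pair of 59-parameter autoencoders fits random labels
to ≈35% training error, i.e. somewhat below chance, purely by
memorization; held-out performance on shuffled labels remains at chance.
This is the expected behavior of an expressive model under a greedy
optimizer and is reported by the acceptance script rather than hidden.

## Evaluation protocol

Stratified train/test splits at configurable training fractions
(defaults 40–80%) and stratified k-fold cross-validation (defaults 6–10
folds) via scikit-learn's splitters; per-split rows report sensitivity,
specificity, accuracy and F-score with tumor as the positive class, plus
a trailing average. Zero-denominator metrics are NaN markers, excluded
from averages with a logged note — silent zeros would distort averages.
For k-fold rows the per-fold confusion matrices are pooled before
computing the row's metrics. Per-image segmentation seeds derive from the
global seed and the item index, so the whole pipeline is deterministic;
feature extraction (stateless per image) is computed once, while feature
scaling and classifier training see only each split's training portion.

Pipeline defaults: Gabor bank as above, K = 2 thresholds (three classes,
matching the phantom structure), per-image EPO budget of population 20 ×
40 iterations — phantom histograms are strongly trimodal and this small
budget already attains the exhaustive optimum — and classifier training
at population 30 × 150 iterations. A 200-phantom end-to-end evaluation
completes in well under a minute on one CPU core.

## Known limitations

- EPO's contraction onto the best agent is aggressive; on deceptive
  multimodal objectives (e.g. Rastrigin in high dimension) it can commit
  early. The MLT objectives it is used for here are low-dimensional
  (K ≤ 3) and benign.
- The classifier's decision rule ignores reconstruction-error calibration
  between classes; with strongly unbalanced feature scales one class's
  autoencoder can dominate. Min–max scaling mitigates this.
- The phantom generator's realism limits are listed above; no claim about
  clinical CT performance follows from these experiments.
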