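# Methods

This note documents the models, conventions and numerical choices behind
`aquilens`, and what the synthetic benchmarks do and do not demonstrate.

## Synthetic image generator

The generator stands in for two stained-tissue benchmarks whose images
cannot be redistributed. It reproduces their class compositions exactly —
`dataset1`: 165 images, 74 benign / 91 malignant; `dataset2`: 1144 images,
536 NT / 345 VT / 263 NVT — and emulates class-dependent texture through
five per-class parameters: expected blob count per 64×64 tile, blob
boundary irregularity (low-order radial harmonics on a disc), background
and blob RGB colours (an H&E-like pink/purple palette), and the amplitude
of a smooth Perlin-like background field (bilinear upsampling of a coarse
Gaussian grid). Malignant-like classes get denser, darker, more irregular
blobs.

A single `separability` knob `s ∈ [0, 1]` linearly interpolates each
class's parameter vector between the pooled mean (s = 0: all classes
identically distributed) and the fully distinct values (s = 1). Class
differences in any texture statistic are therefore monotone in `s` by
construction. Default images are 64×64 px — a deliberate desk-scale choice;
the native resolutions of the emulated sets are carried as profile metadata
only. Each image is rendered from its own `SeedSequence`-spawned generator,
so output is byte-identical for a given (profile, seed) and independent of
generation order.

**What this does not show.** The generator produces class-separable texture
statistics, not realistic histopathology: no staining variation, no tissue
architecture, no scanner artefacts, no label noise. Pipeline accuracies on
these images (100% at s = 1) say the machinery works end to end; they say
nothing about accuracy on real tissue.

**Splits.** Stratified by class with seeded shuffling; the per-class train
count is round-half-up(count × fraction), the remainder goes to test. For
the 165-image profile at 80:20 this yields 132/33 — matching the sample
sizes implied by the published report tables. (Floor-based rounding would
give 131/34.)

## Faster SqueezeNet

Layer inventory: 4 convolutional layers, 3 blocks, 1 batch-norm stage,
global average pooling. Default widths (all overridable via `NetworkSpec`):
conv(16, 3×3, s2) → concat block [fire(8, 8+8)] → conv(32) → concat block
[fire(16, 16+16)] → conv(64) → residual block [fire(16, 32+32)] →
BatchNorm → conv(feature_dim, 1×1) → GAP, feature_dim 128. A concat block
pools its input and a fire-transformed copy and concatenates them along
channels (the dense-style link `x_l = H_l([x_0, …, x_{l−1}])`); the
residual block computes `F(x) + x`, with a 1×1 projection when channel
counts disagree (the ResNet convention). Which block positions are
concat-type vs. residual-type is an open design point; concat–concat–
residual is the documented default.

The trunk is He-initialised under a fixed seed and kept frozen; only the
softmax classifier head is trained (minibatch SGD, inverted dropout on the
feature vector during training only, internal seeded 80/20
train/validation split). This is the quantity the hyperparameter search
tunes, and it keeps a single tuning evaluation under a second on one CPU.
Batch-norm statistics are frozen at (0, 1) unless `calibrate_batchnorm` is
called on a data batch; features are standardised before the head fit.
Divergence is declared when gradients go non-finite or the head weight
magnitude exceeds 1e8 (softmax alone never overflows, so a norm guard is
needed), and carries the offending hyperparameters.

## Adaptive Aquila Optimizer

Minimises a black-box objective over box bounds with four update rules —
expanded exploration `X₁ = X_best(1 − t/T) + (X_M − X_best)·rand`; narrowed
exploration `X₂ = X_best·levy(D) + X_R + (y − x)·rand` with the spiral scan
`r = r₁ + 0.00565·D₁`, `θ = −0.005·D₁ + 3π/2`, `D₁ = 1…D`; expanded
exploitation `X₃ = (X_best − X_M)·α − rand + ((UB − LB)·rand + LB)·δ`;
narrowed exploitation `X₄ = QF·X_best − G₁·X·rand − G₂·levy(D)` with
`QF = t^((2·rand−1)/(1−T)²)`, `G₁ = 2·rand − 1`, `G₂ = 2(1 − t/T)`.
Schedule: exploration while `t ≤ (2/3)T`, exploitation after, picking
within each pair with probability 1/2 (the original Aquila convention).
Lévy steps use the Mantegna construction, σ(β = 1.5) ≈ 0.6966, with scale
s = 0.01 (the classical small-step convention; β and s are independently
configurable). Proposals are clamped coordinate-wise to the bounds;
non-finite objective values reject the candidate with a warning.

Two points were genuinely open and are resolved as follows:

* **Niche sharing direction.** Sharing sums `S_i = Σ_j sh(d_ij)` with
  `sh(d) = 1 − d/ρ` below the radius ρ (default `0.1·‖UB − LB‖`) must
  *worsen* a crowded individual's fitness under minimisation, so the
  adjustment is multiplicative, `F_i' = F_i·S_i` (`F_i/S_i` for negative
  fitness), with the incumbent best exempt. Since every adjusted value is
  ≥ its raw value, the best's rank is never worsened. The penalty enters
  the greedy acceptance threshold: a crowded individual accepts proposals
  more readily and is pushed to search elsewhere, which preserves
  diversity without ever degrading the separately tracked raw-fitness
  best (the trace is non-increasing by construction). A division-based
  variant was tried and rejected: it rewards crowding and, once the
  population converges, effectively freezes acceptance, measurably
  degrading late-stage refinement.
* **Scalar vs. per-dimension draws.** The random factor multiplying `X(t)`
  in the swoop update is drawn per dimension. A scalar draw scales all
  coordinates by one factor, reducing late refinement to a line search
  along the current position and leaving a several-percent error floor in
  anisotropic boxes; per-dimension draws let coordinates refine
  independently. All other `rand` draws are scalars, in the draw order
  documented in each function's docstring (the order is part of the
  contract the oracle tests transcribe).

On the 5-D sphere over [−5, 5]⁵ with N = 20, T = 100 the median best
fitness over ten seeds is ≈ 4e-15.

## Hyperparameter tuning

Search space (defaults; the emulated reporting protocol fixes final
settings — learning rate 0.01, dropout 0.5, batch size 5 — but no tuned
ranges, so these are the package's choices): learning rate log-uniform on
[1e-4, 1e-1], dropout on
[0.1, 0.7], batch size integer on {2…32}. Codecs guarantee
decode(encode(h)) = h for representable h and clamp-and-round semantics
otherwise. The fitness is the validation error percentage after training
the head for 5 epochs (a reduced-budget proxy for the full 50-epoch
setting; the frozen trunk's features are cached so a search of
population 6 × 5 iterations runs in seconds). Divergent settings score the
worst case, 100.

## Recurrent ensemble

The three members read the feature vector as an 8-step sequence
(zero-padded reshape; the pad length is recorded and flattening restores
the input). Cells follow their equations exactly — Elman:
`h_t = σ(P_h h_{t−1} + P_x x_t + B_a)`, `y_t = tanh(P_o h_t + B_o)`; GRU:
reset/update gates and the Hadamard convex combination; BiLSTM: standard
input/forget/output-gate LSTMs in both directions combined per step as
`y_t = tanh(ω₄ o_t + ω₆ o′_t + b_y)`. Training is full
backpropagation-through-time with Adam (default 30 epochs, batch 16,
hidden 24), cross-entropy on a softmax head over the final hidden state
for the Elman and GRU members. For the BiLSTM the head reads the
time-averaged combined output instead: at the final step the backward
layer has seen a single input, so no single step summarises both
directions. Analytic gradients are verified against central finite
differences in the test suite.

Votes: `c = argmax_j Σ_i Δ_ji·w_i`, ties to the lowest class index
(deterministic). Weights default to each member's validation accuracy on a
seeded 20% holdout of the training features, normalised to sum to one;
uniform weighting is available, under which the vote reduces to simple
majority.

## Explainer

Superpixels default to a deterministic √n×√n grid (graph-based Felzenszwalb
segmentation optional). Masked segments are filled with their mean colour —
note this means a region whose entire signal is its mean intensity is
barely perturbed; signals carried by texture/contrast are the intended use
case, as in the planted-region benchmark. Proximity kernel
`exp(−d²/0.25²)` on the masked-fraction distance; 1000 samples by default
(300 suffice for 16 segments in the benchmarks). The surrogate is a
weighted least-squares fit on all mask indicators, restricted to the
`num_features` largest-|coefficient| segments and refit; a singular design
falls back to a small ridge penalty with a warning. On a black box exactly
linear in the mask bits the surrogate recovers the coefficients to 1e-6.
The tabular mode resamples switched-off features from per-feature Gaussian
marginals of the training matrix; zero-variance features stay at their
mean.

## Pipeline and reproducibility

Stages run in fixed order (load/generate → preprocess → features → optional
tuning → ensemble → report → explanations). Preprocessing is resize +
rescale only; no augmentation is applied by default. A master seed fans out to
per-stage seeds via `SeedSequence([master, stage_index])`; the manifest
records the config hash and a digest of the numeric outputs, and identical
configurations yield identical digests.

## Problem sizes used in the shipped benchmarks

Chosen as desk-scale defaults: 64×64 images; 200 images (100/class) for the
end-to-end accuracy benchmark with 5-epoch member training; ten optimizer
seeds for the sphere benchmark; fifty seeded instances at 300 perturbation
samples for the planted-region recovery rate.

## Known limitations

* The convolutional trunk is a frozen random feature extractor; only the
  head and the recurrent members learn. This is sufficient for the
  synthetic benchmarks and keeps the package dependency-light, but real
  histology would need trunk training.
* The one-vs-rest "per-class accuracy = recall" convention matches the
  emulated report tables, not the more common overall-accuracy convention.
* The generator's appearance model is statistical, not morphological
  (no glands, nuclei chains, or necrosis patterns).
* The optimizer handles box constraints only.
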