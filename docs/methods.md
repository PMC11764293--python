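# Methods

## Signal model and preprocessing

Raw fNIRS recordings are two-wavelength light-intensity series
`I(λ, channel, t)`. The chain to network-ready trials is:

1. **Optical density.** `ΔOD(λ,c,t) = −log10(I(λ,c,t) / I_ref(λ,c))`. The
   reference intensity is the per-channel temporal mean (the common fNIRS
   convention; a first-sample reference is selectable). The choice only
   shifts ΔOD by a per-channel constant and is nulled later by baseline
   correction.
2. **Modified Beer–Lambert law.** Per channel and sample,
   `[ΔHbO, ΔHbR]ᵀ = (1/d) · ε⁻¹ · [ΔOD(λ₁)/DPF(λ₁), ΔOD(λ₂)/DPF(λ₂)]ᵀ`,
   with `d` the source–detector distance (default 3 cm), DPF the
   differential path-length factors (default 6.0 at both wavelengths) and
   `ε` the 2×2 extinction-coefficient matrix (rows = wavelengths 760/850 nm,
   columns = HbO/HbR, defaults 1486.6/3843.7 and 2526.4/1798.6
   L·mol⁻¹·cm⁻¹). All constants are configuration fields; the matrix is
   validated for invertibility (condition number < 1e12).
3. **Band-pass.** Third-order Butterworth, passband 0.01–0.1 Hz. The filter
   is applied forward–backward (`sosfiltfilt`), i.e. zero-phase: a causal
   IIR Butterworth is *not* linear-phase, and the distortion-free intent is
   honoured by the two-pass application (squaring the magnitude response; a
   causal single pass is available via `FilterConfig(zero_phase=False)`).
4. **Epoching.** One trial per event, −2 s to +28 s around task onset; at
   the 10 Hz default rate that is 300 samples. Trials whose window leaves
   the recording are dropped and counted, never zero-padded.
5. **Baseline correction.** `BC(x) = x − u₀` with `u₀` the per-channel mean
   over −1..0 s before onset.
6. **Analysis window.** Samples with 0-based index in `[20, 276)` — the
   half-open reading that yields exactly the 256-sample window (a 1-based
   inclusive reading would give 257) and skips the first 2 s to respect the
   delayed hemodynamic response.
7. **ROI selection** over the 20-channel montage:
   A = 1–4, 11–14; B = 5, 6, 15, 16; C = 4–7, 14–17; D = 8, 9, 18, 19;
   E = 7–10, 17–20; FULL = 1–20.

Trials stack ΔHbO and ΔHbR rows per measurement channel (40 feature rows at
the full montage); HbO-only or HbR-only stacking is a config option.

## Network

Input: one trial, `(feature_channels × 256)`.

| stage | operation | output at defaults |
|---|---|---|
| 1 | time-axis affine 256→99, LayerNorm (channel-major throughout) | 40 × 99 |
| 2 | pointwise conv 40→256, GLU | 128 × 99 |
| 3a | depthwise conv, kernel 30, valid; BatchNorm; Swish | 128 × 70 |
| 3b | pointwise conv 128→64; dropout; flatten | 64 × 70 → 4480 |
| 4 | FC 4480→256, dropout; FC 256→128, dropout | 128 |

The classifier head is a single 128→3 linear layer with softmax; the domain
discriminator a single 128→2 linear layer with softmax. Dropout is 0.5.
Swish is `x·sigmoid(x)` with no learnable slope. Weights use uniform
fan-in initialisation, `U(±1/√fan_in)`, from explicitly seeded generators.

The time-axis reduction to 99 samples is the one genuinely open
architectural dimension: it is the unique value for which a valid
depthwise convolution of kernel 30 produces the 70-sample stage-3 output,
and it is isolated in the single config field `time_reduce`. With it, the
default extractor has exactly 1,228,649 trainable parameters (≈1.23 M).

`conv_variant="standard"` replaces the separable pair (3a + 3b) with one
full 128→128 convolution of the same kernel, the standard baseline that
depthwise-separable convolution is meant to replace. The conv-stage weight
difference at kernel 30 is `128·128·30 − (128·30 + 128·64) = 479,488`
(biases excluded from the stage comparison).

**Profiler conventions.** MACs are counted over linear and convolution
layers only — normalisation, activations and dropout excluded —
`FLOPs = 2 × MACs`; depthwise conv MACs are `k · C · L_out` (one input
channel per group). Throughput (samples/s) is `N/T` with `T` the median
wall time over repetitions and is hardware-bound, reported for information
only.

The network runs on a small reverse-mode autodiff engine over numpy
(`fnirsda.autodiff`): tape-based, broadcasting-aware, with fused nodes for
the convolutions (FFT-based circular correlation for the depthwise stage),
the normalisation layers and the GLU, chosen so a batch-128 training step
stays around a quarter second on one CPU core.

## Adaptation objective

`L_all = L_cls + λ(L_MMD + L_domin)` with λ = 0.35.

* `L_cls`: mean cross-entropy of the true class on the source batch.
* `L_MMD`: squared maximum mean discrepancy between source and target
  feature batches — biased V-statistic (non-negative by construction) of a
  Gaussian RBF kernel `exp(−‖x−y‖²/2h)`, summed over bandwidths
  `{¼, ½, 1, 2, 4} ×` the median pairwise squared distance of the pooled
  batch. Bandwidths are treated as constants in the gradient. A fixed
  bandwidth list is available for tests.
* `L_domin`: cross-entropy of the 2-way domain head on the joint batch
  (source label 0, target label 1), mean-reduced — matching the 1/n
  convention of the classification loss.

**Adversarial mechanics.** The minimax between extractor and discriminator
is folded into the single objective by a gradient-reversal operator
(identity forward, gradient × −coefficient backward), so one Adam optimiser
minimises `L_all`: the discriminator head descends its own loss while the
extractor ascends it. Three stabilisations proved necessary and are
defaults:

1. **Unit-norm discriminator input.** With raw features, the extractor wins
   the game by inflating target-feature norms (the domain cross-entropy then
   grows without bound and classification collapses — observed, not
   hypothetical). The discriminator therefore sees L2-normalised features;
   its architecture (one linear layer + softmax) is unchanged.
2. **Warm-up schedule** on the reversal coefficient,
   `coef(p) = 2/(1+e^{−10p}) − 1` over training progress `p` (a constant
   coefficient is selectable).
3. **Learning-rate annealing** `μ(p) = μ₀/(1+10p)^{0.75}` from the initial
   rate μ₀ = 0.001, applied identically to every run — adaptive or plain —
   so ablations remain step-for-step comparable.

With λ = 0 the adaptation branch (target batch draw, MMD, discriminator) is
skipped entirely, which makes a λ = 0 adaptive run bit-identical to plain
supervised training under the same seed — the ablation contract the tests
assert. Per-iteration batching pairs each source mini-batch with an
equal-size target batch, cycling reshuffled target permutations with
replacement when the target set is smaller.

## Training protocol

Adam, initial learning rate 0.001 (annealed as above), weight decay 0,
dropout 0.5, 120 iterations, batch size 128, cross-entropy loss.
"Iterations" are read as epochs over the source set by default; a
gradient-step reading is selectable (`iteration_unit="steps"`). Seeds
fully determine runs: model init, batching, dropout and target sampling use
independent streams spawned from the one seed.

Strategies: **DT** trains on source only and evaluates on all target
trials. **FT** takes the DT model, freezes the extractor, retrains the
classifier head on a stratified 25 % labeled calibration split of the
target (fraction configurable), and evaluates on the disjoint 75 %.
**DA** trains on source labels plus unlabeled target trials with `L_all`
and evaluates on all target trials; target labels never touch the
objective. Paradigms: **MTS** holds each subject out against all others;
**STS** averages over single-source pairs.

## Synthetic data generator

The generator emulates a 30-participant, 20-channel, three-class protocol:
per trial a 2 s introduction, 10 s task, and a rest drawn uniformly from
17–19 s; 25 trials per class per subject in randomised order (all counts
configurable; study-scale defaults). Per channel the continuous ΔHbO signal
sums:

* task-locked responses — a double-gamma HRF (gamma-density lobes with the
  positive mode exactly at `peak_time` = 6 s, undershoot at 16 s with ratio
  1/6, unit peak) convolved with the 10 s task boxcar, weighted by a class
  topography (hand classes activate the contralateral hemisphere's central
  channels, feet the medial channels of both), a per-channel subject gain
  and a subject latency;
* Gaussian noise (sd 1.0 concentration units against a unit-peak response);
* sinusoids at ≈1.1 Hz (cardiac), 0.3 Hz (respiratory) and 0.1 Hz (Mayer)
  with random phases, amplitude 0.5;
* an integrated-random-walk drift (sd 0.3/√s).

ΔHbR is −⅓ × the task-locked ΔHbO delayed by 1 s plus its own noise (the
typical anticorrelation; both constants are config fields). Amplitudes are
in arbitrary micromolar-like units — the pipeline is scale-covariant.

**Domain shift** is parameterised exclusively through subject profiles, so
"shift off" is exactly representable. Severities draw, per subject:
log-normal per-channel gains; a log-normal global amplitude scale; a
latency shift; a log-normal noise-level factor; small iid topography
jitter; and a **montage displacement** — all class topographies shifted by
the same number of channel positions within each hemisphere, emulating
between-subject cap/optode placement differences. Prior widths (log-gain
sd, log-scale sd, latency sd, log-noise sd, jitter sd, displacement set):
none = all zero; mild = (0.4, 0.3, 0.3, 0.2, 0.05, {−1, 0, 1}); strong =
(1.2, 1.0, 0.5, 0.4, 0.05, {−2, +2}) — at the strong level every
subject's cap sits two positions from the reference montage, in a random
direction.

The composition is deliberate. The network's own normalisation layers make
it largely invariant to amplitude scaling, uniform delays and added noise,
so those components barely move cross-subject accuracy; the montage
displacement is the dominant *covariate* shift that survives
normalisation — it relocates every class's spatial pattern coherently, so
it degrades a source-trained classifier while remaining repairable by
marginal feature alignment (the mechanism under test). iid topography
jitter — a label-conditional corruption no unsupervised marginal-alignment
method can repair — is kept small. Calibrated once so that
class-conditional between-/within-subject feature-distance ratios are
≈0.7 at "none" and >2 at "strong" (task-window means of preprocessed
trials).

**What the generator does not emulate:** measurement optics (the intensity
entry point is exercised with synthetic intensities, not a photon-transport
model), motion artifacts, session effects within a subject, or
non-stationary noise. Passing tests therefore demonstrate that the
pipeline, objectives and protocols behave as specified under controlled
shift — not that any particular accuracy will be attained on real
recordings.

## Problem sizes in the test suite

The domain-adaptation-benefit check runs 6 subjects × 15 trials/class,
strong shift, seeds 1–5 (target subject rotating with the seed), 120
epochs, batch 128 — about ten minutes on one CPU core. Fifteen trials per
class is the package's chosen scaled-down size: it keeps enough target
trials (45) for the marginal-alignment terms to estimate a distribution
while holding the full experiment inside a desk-scale budget. Unit tests
use much smaller architectures and datasets; the default architecture
constants are always exercised at full size where the check is about
shapes or counts (which cost nothing).

## Metrics

One-vs-rest TP/TN/FP/FN per class from the 3×3 confusion matrix; macro
averaging for precision, recall and F1 (recall = TP/(TP+FN); F1 reported
as 0 where precision + recall = 0). Cohen's kappa is
`(accuracy − Pe)/(1 − Pe)` with `Pe = Σ_c row_c·col_c / n²`. A class
absent from the truth yields recall 0 with a warning flag. ROC-AUC is
computed one-vs-rest per class (rank statistic, ties averaged), with
degenerate classes flagged NaN and excluded from the macro average.
Computation is delegated to scikit-learn; independent hand-computed oracles
pin the values in the tests.

## Known limitations

* The adversarial game with a single linear discriminator is only stable
  with the normalisation/scheduling described above; removing them
  reproduces the divergence.
* Unsupervised marginal alignment can mis-assign target classes when the
  shift is strongly class-conditional or the target sample is very small;
  the benefit of DA over DT on synthetic data is a mean effect across
  seeds, not a per-seed guarantee.
* The FPS metric depends entirely on the host; it is never used in
  assertions.
* SNIRF input, motion-artifact correction, short-channel regression,
  class-conditional MMD variants and hyper-parameter search are out of
  scope.
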