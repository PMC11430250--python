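# Methods

This note records the modelling assumptions, parameter choices and numerical
conventions behind `dfcgn`, in the spirit of a model-description appendix.

## Synthetic EEG generator

The generator emulates a music-stimulation *protocol*, not brain physiology.
Each recording is a sequence of alternating music and silence blocks
(defaults: five 15 s music blocks per valence class, 15 s silences, 1024 Hz,
channels FP1/Pz/Fz, 20 subjects).  Within a block, the signal is a sum of
band-limited stochastic oscillations in the canonical EEG bands
(delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30, gamma 30–60 Hz), synthesised
as 8th-order Butterworth band-pass filtered white noise.  Music blocks carry
a class-dependent band-power signature; silence blocks carry a neutral one.
A 50 Hz mains sinusoid (amplitude 2 units, random phase per channel) and
white Gaussian noise at a configurable SNR (default 20 dB, defined as
10·log₁₀(P_signal/P_noise) over the music portion) are added on top.
Amplitudes are microvolt-like arbitrary units (oscillatory RMS ≈ 30).

Band sources are shared across channels with per-channel gains ~N(1, 0.1²),
a crude stand-in for volume conduction: it makes inter-channel correlations
high (≈0.9) but not degenerate, which is what the connectivity graph needs.

Because Butterworth pass-bands leak energy across their edges, naively
scaling each source to a target power biases the *measured* in-band ratios
(delta loses ~15% of its energy below 0.5 Hz even at order 8).  The
generator therefore solves a small non-negative least-squares system
M p = target, where M[i, j] is the fraction of band-j source power landing
inside band i (computed from the filters' frequency responses), so that
Welch-estimated in-band ratios match the configured signature in
expectation.  Across a recording's five blocks the realized ratios agree
with the configuration to well within 10%.

Class signatures are modelling choices, not claims about valence: the
default positive class has elevated alpha+beta relative power, the negative
class elevated theta.  A deliberately easy high-contrast variant
(`HIGH_CONTRAST_CLASS_BAND_POWER`, alpha 0.45 vs 0.05 and theta 0.05 vs
0.45) is the fixture for end-to-end demonstrations and sanity checks.  What
passing tests on these data show is that the pipeline can learn band-power
structure from raw waveforms at realistic SNR — not that it would reach the
same accuracy on real recordings, which carry 1/f background, artifacts
(blinks, EMG), non-stationarity and inter-subject variability that the
generator deliberately omits.

## Preprocessing

Channel selection, a 50 Hz IIR notch (quality factor 30 — the conventional
choice; the protocol specifies only the frequency) and a 2nd-order
Butterworth band-pass at 0.5–60 Hz.  Filters are applied zero-phase
(forward–backward with odd-reflection padding) so that epoch boundaries are
not delayed; effective attenuation in dB doubles relative to a single pass.
Epoching takes one 15 s epoch per music block, labelled by the block's
class (positive = 1, negative = 0); an optional non-overlapping window
splitter multiplies training examples (the desk-scale configuration uses
0.5 s windows).  Silence blocks are discarded.

## Graph construction

Nodes are channels; edges are absolute Pearson correlations averaged over
epochs, thresholded at τ = 0.5 with weighted retention (binarisation is
available by flag).  The combinatorial Laplacian L = D − W is used without
symmetric normalisation, with a dense eigendecomposition (N is 3–64 at
most).  Conventions chosen for reproducibility and degenerate inputs:
eigenvalues ascending; each eigenvector's sign fixed by making its
largest-magnitude entry positive; an empty graph (λ_max = 0) defines
L̃ = −I so Chebyshev terms stay well-defined.  Chebyshev orders above 25
are rejected as a numerical-stability guard.

## FT2 activation

The forward map is

    f(σ) = P σ k(σ)   (σ > 0),    f(σ) = N σ k(−σ)   (σ ≤ 0),
    k(σ) = ½ [ 1/(α + (1−α)σ) + (α−1)/(ασ − 1) ],   α ∈ (0, 1).

k(1) = 1 identically, so f(1) = P and f(−1) = −N; with k ≡ 1 the unit is
exactly Leaky-ReLU (exposed as a debug flag, used in regression tests to
isolate the activation's contribution).  Gradients are the exact analytic
derivatives of this map — in particular
∂k/∂α = ½(σ−1)[1/A² + 1/B²] with A = α+(1−α)σ, B = ασ−1 — and are
validated against central finite differences (step 1e-5, relative
tolerance 1e-4, 10³ draws).  Updates use classical momentum
Δγ ← ρΔγ + ξ∂L/∂γ, γ ← γ − Δγ, with α clamped into (0, 1).

k has a pole at σ = 1/α where f grows superlinearly and then flips sign.
Denominators within ε = 1e-8 of zero are clamped sign-preservingly and
counted in a diagnostics counter.  Three measures keep training away from
the pole, all adopted after observing that a pole at σ = 2 (α = 0.5) lets
weight drift push pre-activations into the unstable region:

1. **α initialised at 0.25** (per-layer scalar), placing the pole at σ = 4;
   P starts at 1.0 and N at 0.05 per unit (a Leaky-ReLU-like start; 0.01
   proved prone to dying-layer collapse in deep stacks with max pooling).
2. **Input standardisation + one-shot layer calibration.**  Inputs are
   z-scored per (node, feature) on the training split; then a single
   forward pass on a training sample rescales each layer's weights so the
   *bulk* of its pre-activations has standard deviation 0.3.  The scale is
   a normal-consistent MAD rather than the standard deviation, because the
   pole's heavy tail would otherwise skew the calibration and collapse
   deeper layers.
3. **Gradient norm clipping** (global norm 1.0 by default) plus a per-epoch
   learning-rate decay of 0.9 in the desk-scale configuration, which
   prevents the late-training excursions that otherwise re-enter the pole
   region after convergence.

## Architecture and parameter accounting

The network is dropout (rate 0.2, before the first layer only) followed by
five blocks of [Chebyshev conv (Q = 3) → FT2 → max pool along the feature
axis], a global max over nodes, and a dense softmax head.  The published
ledger lists widths 76,800 → 76,800 → 38,400 → 19,200 → 9,600 → 4,800 with
per-layer weight tensors (Q, F_in, F_out).  Those shapes fold the width
reduction into the convolution; at runtime this package instead uses
width-preserving (square) convolution weights and lets the pooling perform
the reduction (factor = the ratio of adjacent ledger widths: 1 for layer 1,
2 for layers 2–5).  `count_parameters` follows the published convention —
layer i counts Q_i × F_in,i × F_out,i + F_out,i — in exact integer
arithmetic without allocating anything; the full ledger (~29.4 billion
parameters) exists for accounting only.  The flatten/dense head is reported
as weights (4,800 × 2) and bias (2) separately.  The default *runtime*
ledger is 64 → 64 → 32 → 16 → 8 → 4 with the same structure.

## Training and evaluation

Splits are epoch-wise, stratified by class, at 70/20/10 (validation and
test sizes floored globally and apportioned by largest remainder; the
remainder trains).  Epoch-wise splitting of windowed data means windows
from one block can appear in both train and test; results on synthetic data
should be read with that in mind — a subject-wise split would be the
stricter protocol for real recordings.  The published hyperparameters are
the defaults (SGD, lr 1e-4, batch 16, cross-entropy, weight decay 6e-6,
150 epochs); SGD-with-momentum, Adam, Adadelta and Adamax are implemented.
The desk-scale configuration (chosen for a minutes-long run on one CPU)
trains the reduced ledger with Adam at lr 1e-3, decay 0.9, 30 epochs on
1,200 half-second windows from 4 synthetic subjects at 128 Hz.  The
best-validation-accuracy checkpoint is kept (earliest epoch on ties); FT2
parameters train with ρ = 0.9, ξ = 1e-4.

Evaluation builds the confusion matrix with positive = class 1 and derives
accuracy, sensitivity TP/(TP+FN), precision TP/(TP+FP), specificity
TN/(TN+FP), and Cohen's κ = (p_o − p_e)/(1 − p_e) with p_e from the
marginals; the ROC is the score-threshold sweep with trapezoidal AUC.  A
single-class test set yields metrics without ROC/AUC (reported absent).

"Peak coefficient" among the six handcrafted baseline features (mean,
variance, skewness, kurtosis, peak coefficient, power) is read as the crest
factor, peak/RMS; a peak-to-peak variant is available by flag.  Baselines
(KNN, SVM, MLP) are scikit-learn pipelines with standardisation.

Noise robustness is probed in the signal domain: white Gaussian noise
scaled per epoch to a stated SNR is added to the *test* epochs of a
clean-trained model, averaged over 5 noise seeds per SNR.  The original
robustness experiments used acoustic ambient noise during recording; the
signal-domain sweep is the desk-scale analogue and should be read as an
approximation.

## Reproducibility and degenerate inputs

All randomness flows from explicit seeds (per-subject streams derive from
the dataset seed via `SeedSequence`); equal configuration + seed reproduces
every artifact byte for byte, and each output carries a configuration hash.
Zero-variance channels yield zero correlations (with a warning) and zeroed
scale-free statistics; an all-silence schedule yields an empty epoch set
rather than an error; empty graphs, single-class test sets and non-finite
losses are handled explicitly as described above.

## Known limitations

- The generator omits 1/f background, artifacts and non-stationarity;
  accuracies on it do not transfer to real EEG.
- Epoch-wise (not subject-wise) splitting inflates synthetic test accuracy
  relative to a cross-subject protocol.
- FT2 training remains sensitive near its pole: the stabilisers above make
  the desk-scale runs reliable, but occasional late-training instability is
  still visible in loss traces (the validation-checkpoint rule absorbs it).
- The full-scale ledger is supported for accounting, not execution.
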