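# Methods

`scalonet` implements a screening pipeline for Parkinson's disease (PD) from
resting-state EEG: per-channel continuous wavelet scalograms are cut into
128×128 grayscale images, a convolutional network classifies each image, and
Grad-CAM heat maps show which time–frequency regions drove the decision.
This note documents the model, its parameters, the synthetic data used for
validation, and the numerical choices made where the design was open.

## Signal model and time–frequency front end

Each analysis channel x(t) is transformed with the continuous wavelet
transform using an analytic Morlet mother wavelet,

    X(s, τ) = (1/√s) ∫ x(t) ψ*((t − τ)/s) dt,
    ψ(t) = π^(−1/4) e^(iω₀t) e^(−t²/2),

with center angular frequency ω₀ = 6 (configurable). Scale is reciprocal to
Fourier frequency, f = ω₀·fs/(2π·s) for a dimensionless scale in samples;
larger scales mean lower frequencies. The transform is evaluated through
MNE's Morlet machinery (`n_cycles = ω₀` reproduces the parameterization
above); convolution zero-pads at the boundaries and boundary columns are
retained — no cone-of-influence trimming, since the downstream classifier
sees every column.

The scale grid is 138 geometrically spaced scales whose equivalent
frequencies span 1–60 Hz at fs = 512 S/s, covering the delta (1–4 Hz)
through gamma (35–45 Hz) bands. Neither the grid spacing nor its range is
canonical; geometric spacing gives constant relative bandwidth per step
(ratio ≈ 1.030 between neighbours), and both endpoints are configurable.

Each per-recording-per-channel magnitude matrix |X(s, τ)| is min–max scaled
to [0, 1] **as a whole** before tiling, so all tiles from one
recording-channel share one intensity frame; a constant matrix maps to all
zeros. The 128 lowest scales (the highest frequencies) of the 138 are kept,
and the time axis is split into consecutive non-overlapping 128-column
windows, dropping the final partial window. A 120-s recording at 512 S/s
thus yields ⌊61440/128⌋ = 480 tiles per channel. Tiles export as 8-bit
grayscale PNG (pixel = round(value·255)); re-import is exact to 1/255.

A known bias of this front end: with unit-energy (1/√s) wavelets, the
scale-profile peak for a pure tone sits ≈ 1.4 % below the tone frequency
(the √s envelope skew). That is within one step of the default grid and is
measured, not corrected.

## Classifier

The reference network takes one 128×128×1 tile through three convolutional
blocks — four 11×11 convolutions at depth 32, four 9×9 at 64, four 7×7 at
128, every convolution same-padded and ReLU-activated, every block closed by
a 2×2 max pool — then dense ReLU layers of widths 128, 64, 32, 16 and a
final softmax layer over 2 or 3 classes. The spatial chain is
128 → 64 → 32 → 16, so the head sees a 16×16×128 feature map. Counting
convolutions (12), pools (3) and dense layers (5) gives the nominal 20
layers; input and elementwise activations are not counted. `describe()`
emits this audit.

Training is plain SGD on the softmax cross-entropy: batch size 50, learning
rate 1e-5, 40 epochs by default, shuffled mini-batches (the final short
batch is used), He-uniform initialization, zero biases, no augmentation, no
early stopping, no input standardization beyond the [0, 1] tile scale.
Momentum is exposed but defaults to 0. Every model in a cross-validation
run is freshly initialized per fold. Runs are bit-deterministic for a fixed
seed on one machine.

The layers are implemented directly in NumPy (einsum contractions over
sliding-window views for the convolutions); gradients are verified against
central finite differences to ~1e-9 relative in the test suite. Because a
full-size network is expensive on one CPU core, `CnnSpec.reduced()`
provides a CPU-scale preset with the same three-block topology: one
convolution per block at depths 4/8/16, kernels 5/5/3, a 2×2 max-pool stem
that halves the input first, and a 32/16 head. All reduced-scale
experiments in the tests and the acceptance script use this preset with an
elevated learning rate (0.05) and ≤10 epochs; the full architecture is
still constructed and audited end-to-end.

Decision rule: binary problems predict the disease class when its softmax
probability is ≥ 0.5 (ties to positive); multi-class uses argmax with
lowest-index tie-break. The threshold is configurable — no canonical value
exists for it.

## Evaluation

Cross-validation is subject-wise: subjects (not tiles) are dealt into k
folds, shuffled within class and assigned round-robin so folds stay
approximately class-balanced even with 15–16 subjects per class. No
subject's tiles can appear on both sides of a fold; an audit re-derives
this from the prediction log.

Metrics per fold and pooled over folds: accuracy = trace/total; binary
sensitivity TP/(TP+FN) and specificity TN/(TN+FP) with PD as positive
(multi-class: per-class one-vs-rest plus macro averages); zero-denominator
cases are NaN, never 0. Quadratic weighted kappa is
K = 1 − Σw·c / Σw·p with w(i,j) = (i−j)², c the normalized confusion matrix
and p the outer product of its marginals; a sign-indefinite linear variant
(w = i−j) exists behind a flag for comparison but is not the default. ROC
curves use a threshold sweep; AUC equals the Mann-Whitney rank statistic
with ties counted half. Reports always carry both the mean-over-folds of
each metric and the pooled-confusion metrics, labeled, because the two
differ in general.

## Synthetic cohorts

The generator emulates the acquisition setting of the public UC San Diego
resting-state cohort: 32 channels (10-20 montage including Fp1, FC1, CP5,
Fp2), 512 S/s, 120 s per recording, 16 healthy controls (HC) and 15 PD
patients each contributing an OFF- and an ON-medication recording (46
recordings). Each channel is

    x(t) = A_bg · n_{1/f^α}(t) + Σ_bands (a_b/√3) Σ_{m=1..3} sin(2πf_m t + φ_m) + σ ε(t),

a unit-variance 1/f^α background (α = 1), three sinusoidal oscillators per
band with frequencies uniform in the band and uniform phases, and white
noise (σ = 0.25). Default class contrast follows the spectral literature on
non-demented PD: OFF medication doubles theta amplitude and halves beta and
gamma relative to HC; ON medication sits at the elementwise midpoint.
A `strong_contrast_spectra()` preset widens these gaps (theta 0.3 vs 3.0,
beta 2.0 vs 0.2, reduced background/noise) for separability experiments.
All band amplitudes are in arbitrary units — only ratios matter after the
scalogram min–max scaling. A master seed fans out through
`numpy.random.SeedSequence` to per-subject, per-channel substreams.

What this emulates: class-dependent band power over a 1/f background at the
study's sampling geometry. What it does not: artifacts (eye blinks, muscle),
nonstationarity beyond band mixing, phase–amplitude coupling, volume
conduction, inter-channel correlation. A pipeline that separates these
cohorts demonstrates that the scalogram → CNN path can recover band-power
contrasts under subject-wise validation — not that real PD EEG is this
separable.

## Reference experiments and problem sizes

The packaged separability experiment uses 8 HC + 8 PD-OFF subjects, 60 s of
one channel each (240 tiles/subject, 3840 tiles), strong contrast, 4-fold
subject-wise CV, the reduced network, 4 epochs at learning rate 0.05.
These sizes are the package's CPU-scale reference configuration; at them
the experiment finishes in minutes on a single core. The permuted-label
control reruns the identical pipeline after permuting the subject → class
assignment; its accuracy is compared to chance with a subject-level
binomial standard error (√(0.25/n_subjects)), since tiles within a subject
receive nearly identical predictions and tile-level SEs would be
meaninglessly small.

## Grad-CAM

For class c, the gradient of the class score y^c (the pre-softmax logit by
default; the softmax probability behind a flag) with respect to the
activations A^k of the last max-pooling layer — the last
non-fully-connected stage, 16×16×128 in the reference network — is averaged
into one weight per feature map, w^c_k = (1/S)·Σ_ij ∂y^c/∂A^k_ij with
S = 256, and the map is ReLU(Σ_k w^c_k A^k). Display maps are bilinearly
upsampled to 128×128 and min–max scaled (all-zero maps stay zero); raw
values are preserved.

A caveat the tests document: the globally averaged weights assume the
network's evidence is position-invariant. A detector trained on a feature
at one fixed position with a dense head can carry localized positive
gradients yet a negative global average, ReLU-ing the whole map to zero.
The localization experiment therefore trains on randomly positioned
planted features, the regime the method assumes (and the regime of real
scalograms, where oscillatory signatures drift along the time axis).

## Known limitations

- The full 20-layer network is constructed, audited and differentiated, but
  not trained at full scale in the packaged experiments; NumPy on one CPU
  is orders of magnitude short of that workload.
- The BrainVision reader covers the standard binary dialect the public
  datasets use, through MNE; exotic dialects are untested.
- No preprocessing (filtering, re-referencing, artifact rejection) is
  applied anywhere — deliberately, as the pipeline under study defines
  none; a hook exists where one would slot it in.
- Scalogram min–max scaling is per recording-channel; inter-subject
  amplitude differences are therefore removed by design, and the classifier
  sees only within-recording spectral structure.
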