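# Methods

## Scope and data model

`emofuse` analyses trial-based three-class emotion experiments: each
trial is two minutes of synchronized 6-channel prefrontal EEG (FP1, FP2,
F3, F4, F7, F8 at 512 Hz), single-lead ECG and skin conductance (both
500 Hz), with a condition label (positive / neutral / negative) and SAM
self-ratings on the 1–9 valence and arousal scales. The default design
is 20 participants × 3 conditions × 6 trials = 360 trials, balanced by
construction. Raw recordings of this kind are rarely shareable, so the
package ships a generative model of the same statistical structure; all
statistical machinery and the classifier operate identically on real
feature tables.

## Synthetic generator

The generator is built so that every feature the pipeline extracts has a
known, steerable expectation, and every transient event is recorded as
ground truth ("no silent events": if an event cannot in principle be
recovered by the pipeline's own detector, the generator does not inject
it — see resolvability below).

**EEG.** Each channel is 1/f-amplitude background noise (10 μV RMS,
spectrum flattened below a 1 Hz knee, since AC-coupled hardware has
already removed slower drift) plus a narrowband 8–13 Hz alpha component
(band-passed white noise, 12 μV RMS). The per-pair asymmetry shift `s`
multiplies right/left alpha power by `exp(±s/2)`, so the generated power
ratio is `exp(s)` in expectation. Optional artifacts: eye blinks
(100–400 μV slow transients on FP1/FP2, Poisson at a configurable rate,
default 0 — see Amplitude rejection), 50 Hz power-line pickup (2 μV),
and ECG measurement noise. Note that average referencing mixes the six
independent alpha processes, which attenuates the extracted asymmetry to
roughly 80 % of the injected value with near-zero frontopolar shifts;
this is a genuine property of referenced montages, not a generator
error, and the recovery tests account for it by testing against a
±0.15 band.

**Cardiac rhythm.** RR(t) = rr_mean + a_LF·sin(2π·0.1t) +
a_HF·sin(2π·0.25t) + white jitter. The variance partition is solved from
the targets: SDNN² splits into a jitter share (chosen as
`clip(0.04·sampen_target², 0.02, 0.8)` — sample entropy is governed by
the jitter-to-tolerance ratio `jitter_sd/(0.2·SDNN)`, and this mapping
keeps the three conditions on the steep part of the entropy curve rather
than in saturation) and an oscillatory share divided between the two
sinusoids in the LF/HF target ratio. The broadband jitter leaks into
both spectral bands, so extracted LF/HF is compressed toward 1 relative
to the target; orderings are preserved. Ectopic beats multiply an
interval by 0.6 or 1.5 (guaranteed >20 % deviation) with probability
0.02 per beat. The ECG is a sum of Gaussian P-QRS-T deflections (R ≈
1 mV) centred on the beat times, with a 0.4 s margin at both trial edges
so every complex lies fully inside the trial.

**Electrodermal activity.** Tonic level plus slow sinusoidal drift, with
phasic responses as biexponential kernels (rise τ = 1 s, decay τ = 4 s)
arriving as a renewal process: a refractory gap of 8 s plus an
exponential tail whose mean preserves the configured events-per-minute
rate. Amplitudes are 0.15 μS + Exp(0.15 μS), the typical range of
spontaneous responses. Two resolvability constraints make ground-truth
counts exactly recoverable by the trough-to-peak detector: events end
6 s before the trial boundary, and an amplitude floor
`prev_amp·(e^(−g/4) − 4e^(−g))` (g = gap) guarantees that a response's
maximum rise slope exceeds the previous response's decay slope — a
response below that floor produces no local extremum at all after the
0.3 Hz low-pass and would be invisible to any turning-point rule.

**Condition profiles (defaults).** Asymmetry shifts (FP2/FP1, F4/F3,
F8/F7): positive (0.05, 0.50, 0.40), neutral (0, 0, 0), negative
(−0.05, −0.50, −0.40) — the frontopolar pair intentionally carries
almost no effect. RR mean 800/820/750 ms; SDNN targets 55/50/30 ms;
LF/HF targets 1.5/1.8/4.0; sample-entropy targets 1.8/1.6/1.0; SCR rates
3/1.5/6 per minute; tonic SCL 5/4/8 μS. SAM profiles pool the
per-category means and RMS SDs of the embedded 18-clip stimulus norm
table. Between-participant trait offsets (asymmetry SD 0.15, RR mean SD
40 ms, SCL SD 0.8 μS) and within-participant trial-to-trial variability
(asymmetry SD 0.30; multiplicative lognormal noise on SDNN (σ = 0.38),
LF/HF (σ = 0.50) and SCR rate (σ = 0.55); SCL SD 1.4 μS) are calibrated
once so that class separation is strong but imperfect — nested-CV
accuracy lands near 90 % with the negative class best recognized —
rather than trivially saturating. All of these are `SynthConfig` fields.

## Preprocessing

* **EEG**: channels with SD > 5× the median channel SD are marked bad
  and excluded from the average reference; 50 Hz notch (Q = 30);
  0.05–100 Hz band-pass (the hardware band re-applied digitally). The
  ±100 μV amplitude-rejection rule is evaluated outside a 0.5 s guard at
  each epoch edge, where zero-phase filter transients would otherwise
  masquerade as artifacts. Automated rejection replaces manual ICA
  component inspection — a deliberate fidelity trade for
  reproducibility; slow ocular artifacts large enough to matter are
  caught by the amplitude rule instead.
* **ECG**: Pan–Tompkins in its classic stages (5–15 Hz band-pass,
  five-point derivative, squaring, 150 ms moving-window integration,
  adaptive dual thresholds with 200 ms refractory and 1.66×RR
  search-back), with fiducials relocated to the raw-ECG maximum within
  ±50 ms. The digital band is 0.5–35 Hz, matching the acquisition
  hardware. Ectopic correction is a single left-to-right pass comparing
  each interval with the last accepted (corrected) value; an interval
  deviating strictly more than 20 % is linearly interpolated toward the
  next compatible interval. The pass is idempotent, and trials needing
  correction of more than 20 % of beats are flagged low-quality.
* **GSR**: order-4 zero-phase Butterworth low-pass at 0.3 Hz, then
  z-scoring with mean/SD pooled over all of a participant's trials
  (label-blind), so between-condition level differences survive
  normalization while between-participant baseline differences do not.

All IIR filtering is zero-phase (forward–backward). Filter family and
order (Butterworth, order 4 unless stated) are package choices; the
analysis contract fixes only the corner frequencies.

## Features

Eleven features, computed on the full trial and on sliding windows
(default 60 s window, 20 s hop → 4 steps per trial; the windowed
sequence exists to give the sequence classifier a temporal axis, while
group statistics use the full-trial values):

* **Alpha asymmetry**: the channel is resampled to 128 Hz and passed
  through a five-level wavelet-packet decomposition (db8), giving 2 Hz
  terminal bands; the 8–14 Hz nodes (closest dyadic cover of the alpha
  band) are reconstructed and the power is the mean squared amplitude.
  db8 rather than a shorter wavelet keeps boundary-frequency loss below
  15 % (a 10 Hz tone, on a node boundary, recovers ≈ 93 % of its power;
  db4 loses ≈ 20 % there). AI = ln(P_right) − ln(P_left) per pair. For
  efficiency the alpha band is reconstructed once per trial and windows
  slice the reconstruction; on the full trial this is exactly the
  per-segment computation.
* **HRV**: SDNN (n−1 denominator) and RMSSD; LF (0.04–0.15 Hz) and HF
  (0.15–0.40 Hz) band powers from a Welch PSD (64 s segments, 50 %
  overlap) of the cubic-spline 4 Hz resampled tachogram, and their
  ratio; sample entropy with m = 2, r = 0.2·SD (Chebyshev distance,
  self-matches excluded). Band edges and (m, r) follow standard HRV
  conventions.
* **Electrodermal**: SCL = mean of the z-scored signal over the window;
  NS.SCRs counts trough-to-peak responses on the phasic component
  (signal minus a 4 s moving median, evaluated on a 20 Hz decimated
  copy — the 0.3 Hz low-pass leaves nothing faster). A response is a
  local minimum followed within 5 s by a local maximum rising at least
  0.01 μS (converted to z-units through the stored normalization SD).
  Two refinements handle the artefacts of this baseline: flats are
  treated as falling so a rise out of quiet baseline still registers a
  trough, and a candidate is suppressed when a ≥1.5× larger candidate
  follows within 7 s — the zero-phase low-pass smears a large response's
  foot up to ~6 s backwards, creating a small spurious bump there, while
  genuinely distinct responses in the generator are at least 8 s apart.
  Real recordings with closely spaced unequal responses would have the
  smaller one merged; the 0.01 μS floor and 4 s median window follow the
  analysis contract.

Undefined values (e.g. sample entropy with no template matches, LF/HF
with zero HF) are NaN-flagged and imputed with training-fold medians
inside cross-validation — never with statistics that touch test data.

## Screening

Trials are aggregated to participant × condition means (the F statistic's
degrees of freedom, (2, 38) at n = 20, identify the participant as the
observational unit), then a one-way repeated-measures ANOVA per feature:
SS_error = SS_within − SS_subjects, F = MS_cond/MS_error. The
Greenhouse–Geisser epsilon comes from the double-centred condition
covariance, ε = tr(S̃)²/((k−1)tr(S̃²)), clipped to [1/(k−1), 1]; selection
uses the ε-corrected p at α = 0.05 (the corrected p is used always, the
conservative choice, rather than gating on a sphericity pre-test).
Partial η² = SS_cond/(SS_cond+SS_error). Tukey HSD post-hoc tests use
the omnibus MS_error: q = |mean_i − mean_j|/√(MS_error/n) against the
studentized-range distribution. If fewer than two features pass in a
fold, the three smallest-p features are kept instead (logged) so PCA has
an input; degenerate designs (zero error variance with a non-zero
effect) are flagged undefined rather than reported as infinite F.

## Dimensionality reduction and classifier

Selected window features are standardized on training-fold statistics
and pooled across windows for PCA: eigendecomposition of the sample
covariance, components kept until cumulative explained variance reaches
90 %, eigenvector signs fixed (largest-magnitude entry positive) for
determinism. The same projection applies to every window, preserving
the sequence.

The classifier is a single-layer LSTM (96 hidden units) over the T × k
score sequence, followed by fully connected ReLU layers 128–64–32 with
dropout 0.4–0.3–0.2 and a 3-way softmax. It is implemented directly in
numpy — gates f, i, c̃, o with the standard sigmoid/tanh recurrence,
batched backpropagation through time, Adam (lr 0.001, β = 0.9/0.999),
gradient-norm clipping at 5, mini-batches of 32, reduce-on-plateau decay
(factor 0.5, patience 5, floor 1e−5) and early stopping (patience 10)
on validation loss with best-weight restoration. The seed drives weight
initialization (uniform ±1/√H gates with forget bias 1, He-initialized
FC stack), batch order and dropout masks, so training is bit-reproducible.
Baselines (RBF SVM with C = 1 and γ = 1/k; random forest, 500 trees;
kNN, k = 5; gradient boosting, 300 rounds, depth 4, η = 0.1) receive the
PCA scores averaged over windows, since they are not sequence models,
and see exactly the same folds and screened features.

## Cross-validation

Outer stratified five-fold split at trial level (each class dealt
round-robin after a seeded shuffle; fold class-counts differ by at most
one). Within each fold a stratified 15 % of the training portion is held
out for early stopping, giving an effective 68/12/20 train/validation/
test split. Screening, imputation, standardization, PCA and all training
consume only training rows; the test fold is touched once, for
evaluation. A sentinel test corrupts every test-fold value after
splitting and asserts bit-identical screening output, PCA components and
training history. Accuracy is reported as mean ± SD (n−1) over folds;
model comparisons are paired t-tests on fold accuracies (df = 4) with
Bonferroni correction over the four baseline comparisons and paired
Cohen's d (mean difference / SD of differences). A participant-grouped
split is *not* the default: the trial-wise design places a participant's
trials in both training and test folds, so reported accuracy measures
within-cohort discrimination, not generalization to new people.

## What the synthetic data does and does not show

The generator reproduces the class-conditional structure of the features
(directions and rough magnitudes of the condition contrasts, participant
heterogeneity, trial-to-trial autonomic variability, balanced design)
and supplies exact event-level ground truth. It does not emulate real
EEG source geometry, movement or electrode artifacts beyond the simple
blink/power-line models, non-stationary within-trial emotional dynamics,
or cross-feature dependencies beyond those the shared profile induces.
Passing tests therefore demonstrate that the pipeline is correct and
leakage-free and that it recovers known structure at realistic
signal-to-noise ratios; they do not certify classification accuracy on
any particular real cohort.

## Problem sizes

The default study-scale dataset used in tests (360 two-minute trials at
full sampling rates) generates and extracts in about a minute on one
core; the full nested CV with all five models adds seconds. Detector
validation suites (R-peak recovery, SCR count exactness, asymmetry
recovery) use 30–120 trials per check, enough for the binomial margins
in their assertions.
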