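# Methods

## Problem and pipeline

`megsense` asks how few MEG gradiometers are needed to decode which of five
phrases a participant is imagining or speaking, and which sensors those are.
The motivation is practical: wearable OPM-based systems carry far fewer
sensors than a 196-gradiometer cryogenic array, so a decoder that keeps its
accuracy on a handful of well-chosen channels is a prerequisite for portable
speech BCIs.

The pipeline is, in execution order:

1. **Synthetic epoch generation** (`synth`) — multichannel trials with
   planted, known class structure (no public dataset exists for this
   protocol, so ground truth is manufactured).
2. **Signal conditioning** (`preprocess`) — 4th-order Butterworth low-pass
   below 250 Hz (zero-phase), 60 Hz notch with harmonics, resampling to
   1 kHz, automated channel/trial rejection, balancing to 60 trials per
   phrase, and extraction of the 1-s analysis window (imagination 1–2 s or
   production 2–3 s after stimulus onset).
3. **Feature extraction** (`features`) — 7-level db4 DWT per channel;
   d1/d2 discarded; d3–d7 and a7 reconstructed alone and mapped to
   high-gamma / gamma / beta / alpha / theta / delta; one RMS value per
   band per sensor per trial. 196 sensors × 6 bands = 1176 features.
4. **Decoding** (`decode`) — SVM with 2nd-order polynomial kernel
   (`(γ·x·x′ + 1)²`, γ = 1/(n_features·var), C = 1, one-vs-one),
   stratified 5-fold CV (48 train / 12 test per phrase per fold), feature
   z-scoring fit on training folds only.
5. **Forward sensor selection** (`select`) — greedy wrapper: step 1
   cross-validates every sensor's 6-feature block alone; step t appends
   each remaining sensor to the fixed optimal set and keeps the argmax;
   plateau = first step whose successor's accuracy strictly decreases.
6. **Stacked sparse autoencoder** (`autoencoder`) — greedy layer-wise
   pretraining (600/300/54 sigmoid units at full scale) with
   MSE + L2 + KL-sparsity loss, then supervised softmax fine-tuning; the
   54-dim embedding (the feature size of 9 sensors) feeds the same SVM.
7. **Reporting** (`report`) — across-subject curves, axial sensor maps,
   condition summaries with paired t-tests, cross-subject consensus (mode)
   counts.

## The synthetic generator

Each trial is background noise (white Gaussian by default; 1/f optional)
with class-specific band-limited oscillatory bursts added on the planted
sensors inside both task windows. Bursts are white noise passed through a
4th-order Butterworth band-pass and scaled so their *expected* RMS equals
the target amplitude; the realised power of a 1-s burst then fluctuates
naturally (strongly for narrow bands), as real oscillatory power does. On
top of that, each burst's amplitude is jittered log-normally
(σ = 0.25, median-preserving) to emulate trial-to-trial cortical power
variability.

The default planted map distributes class information: nine informative
sensors (evenly spaced over the array), each oscillating in one fixed band
(rotating through the five bands at or above theta; delta is reserved for
background and blink-like artifacts), active for *every* class but at a
class-dependent amplitude level cycling through 0.5–1.0× the nominal
amplitude (2× the background sd). A single sensor's graded levels overlap
between classes, so one sensor decodes five phrases only weakly (~40% at
the 50-sensor test scale) and accuracy accumulates as sensors with
complementary level patterns are added, reaching ~85% around 9–13 sensors
— above the all-sensor baseline (~75%), which dilutes the signal across 41
noise sensors. This reproduces the qualitative selection-curve shape the
method exists to exploit: rise, plateau near the planted count, selected
subset ≥ full array. Binary on/off plants with exactly normalised bursts
do not reproduce it (three sensors then saturate the decoder), which is
why the generator uses graded, jittered signatures.

What the generator does **not** emulate: forward-model field spread
(planted effects are confined to single channels, so spatial leakage
between neighbours is absent), head movement, physiological ECG/EOG
channels, and realistic inter-subject anatomy. Passing recovery tests
therefore show that the selection machinery finds sensors that carry
information — not that it would overcome field spread on real recordings.

## Numerical and design choices

- **Hemisphere convention**: the lateral coordinate is x; x < 0 is left.
  Layouts place equal sensor counts on each side of an upper 10-cm shell.
- **Zero-phase filtering** throughout (forward–backward), so time-locked
  windows are not latency-shifted. The notch uses Q = 30 with ~1 s
  filtfilt padding; the default padding is far too short for narrow
  notches and leaves edge transients.
- **Filtering precedes resampling**; the 250 Hz low-pass doubles as the
  anti-alias filter and `resample` refuses to upsample.
- **Trial rejection** measures each trial's peak on the < 4 Hz
  ("blink-band") filtered signal against 8× the median channel sd. Ocular
  and movement artifacts are large slow transients, so this automated
  criterion — a surrogate for manual/EOG-based inspection — separates them
  cleanly from strong task-band oscillations, whose broadband peaks can
  otherwise reach artifact amplitude on unlucky trials.
- **Channel rejection**: flat if sd < 1e-6, noisy if the log-variance
  z-score across channels exceeds 5; calibrated so clean generator output
  loses nothing.
- **DWT boundary handling**: symmetric padding; band reconstructions are
  single-level inverse DWTs truncated to the input length, so the six kept
  bands plus the discarded d1/d2 sum exactly to the input. The dyadic
  edges at 1 kHz (62.5/31.25/15.6/7.8/3.9 Hz) are the operative cut-offs
  behind the nominal band names, and db4 is not brick-wall: power sitting
  exactly on a dyadic edge legitimately splits between adjacent levels,
  which is why oracle checks draw band-limited inputs from band interiors.
- **Kernel form**: the inhomogeneous polynomial `(γ·x·x′ + 1)²`. The
  homogeneous variant (zero constant) is invariant to sign flips of its
  input, so two z-scored clusters mirrored through the origin — exactly
  what binary class structure produces after centring — are inseparable in
  principle. The constant term restores odd-order information and matches
  the conventional polynomial kernel of the major SVM toolboxes.
- **Fold hygiene**: fold assignment is drawn once per dataset
  (stratified, seeded) and reused across every sensor subset within a
  selection run and across AE folds, so step-wise and condition
  comparisons are paired. Scaler and autoencoder are refit on training
  rows of each fold; encoding never sees labels.
- **Selection tie-break**: candidates are scanned in sensor order and only
  a strictly better accuracy replaces the incumbent, so ties resolve to
  the lowest sensor index — deterministic across runs and evaluation
  orders.
- **Autoencoder loss and optimisation**: the sparse reconstruction loss is
  `Σ_dims (x−x̂)² / n + ½λ‖W‖² + β·Σⱼ KL(ρ‖ρ̂ⱼ)` — squared error summed
  over feature dimensions, averaged over samples. The summation convention
  matters: the usual sparse-AE hyperparameter ranges (λ ~ 1e-3, β ~ 1–4)
  balance against a per-sample *summed* reconstruction term, and an
  element-wise mean (smaller by d_in) lets the KL penalty collapse every
  hidden unit to a constant. Logistic-sigmoid encoder/decoder, analytic
  gradients, full-batch L-BFGS, Glorot initialisation, mean activations
  clipped to [1e-8, 1−1e-8] inside the KL term. The loss defines the
  method; any monotonically convergent full-batch optimiser is
  interchangeable here. Pretraining defaults to ≤ 400 iterations per layer
  — enough for ~50-sensor inputs at moderate accuracy, while wide inputs
  benefit from more (the parity comparison below uses 600); fine-tuning
  runs ≤ 200 with a small (1e-4) ridge on all weights, and stronger
  fine-tune regularisation measurably hurts. Inputs are min–max scaled to
  [0,1] per column, fit on training rows, so the sigmoid decoder's range
  covers its targets (a whole-matrix variant is available but loses
  resolution when a few columns dominate the range). Default regularisers:
  λ = 0.002 (centre of the useful 0.001–0.004 range), β = 4, sparsity
  targets 0.20/0.15/0.10 for the three layers; λ and the architecture
  widths are per-dataset configuration, mirroring per-subject tuning at
  full scale.
- **Degenerate paired t-tests** (zero-variance differences) are flagged
  rather than raising: identical vectors report t = 0, p = 1; a constant
  non-zero shift reports ±∞ with p = 0.

## Problem sizes used in tests and the acceptance script

Full-array structural checks run at the nominal 196-sensor / 1176-feature
scale on a handful of trials. Behavioural checks run on scaled-down
arrays the package treats as its standard desk-scale conditions: 20
sensors × 300 trials for chance calibration (20 label permutations), 8
sensors for brute-force greedy equivalence, and 50 sensors (9 planted + 41
nuisance) for selection recovery (nominal amplitude 2× noise sd, default
jitter) and for the autoencoder-vs-9-sensor parity comparison. Parity is
assessed under strong-effect conditions — amplitude 3× noise sd with low
(σ = 0.1) power jitter — where class structure is close to noiseless and
both routes approach their ceiling; at the default jitter the generator's
level-coded classes cap every decoder near 85% and the embedding cannot
match oracle-style sensor selection, because planted signals occupy
single uncorrelated columns (no field spread) and compression has no
redundancy to exploit. The parity stack is 250/120/54 with λ = 0.001 —
the embedding width (54) is kept at full scale, the two upstream layers
scale with the 300-column input. Synthetic data for these runs is
generated directly at 1 kHz; the raw-rate (4 kHz) conditioning chain is
exercised separately by the filter/resampling tests.

## Known limitations

- Planted effects are single-channel; no spatial mixing, so consensus
  analysis across synthetic "subjects" (independent seeds sharing a
  planted map) is easier than across real heads.
- The greedy wrapper is O(n_sensors × K) CV evaluations; at the full 196
  sensors × K = 50 it is hours of single-core compute. Candidate
  evaluations within a step are independent and safe to parallelise.
- Plateau detection by first strict decrease is noise-sensitive by
  construction; the across-subject-mean reading of convergence is
  available via `report.selection_curve` + `find_plateau` on the mean.
- The autoencoder's per-subject regulariser grids are exposed as
  configuration, not searched automatically.
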