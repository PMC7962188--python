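# Methods

`wavebp` estimates a continuous arterial blood pressure (ABP) waveform, in
mmHg, from a fingertip photoplethysmogram (PPG) sampled at 125 Hz, using a
1-D U-Net trained on aligned 256-sample window pairs. This note records the
model, the numerical choices, and what the synthetic test-bed does and does
not establish.

## Signal model and preprocessing

**Band-pass filtering.** The PPG is filtered to 0.5–8 Hz with a linear-phase
equiripple (Parks–McClellan) FIR band-pass; content below 0.5 Hz is treated
as baseline wander and above 8 Hz as high-frequency noise. The ABP channel
is not filtered — it is the regression target in physical units. Design
parameters: transition bands 0.2→0.5 Hz and 8→8.5 Hz, linear ripple targets
0.02 per band, tap count from the Bellanger order estimate for the narrower
transition (667 taps at fs = 125 Hz), rounded up to odd so the impulse
response is exactly symmetric. Two non-obvious numerical constraints drove
these values:

* scipy's `remez` exchange loses numerical stability near the ~835 taps that
  a 0.01-ripple design would need; the 0.02 target keeps the design
  well-conditioned. The filter is applied forward–backward (`filtfilt`), so
  the effective response is squared: ~66 dB stop-band attenuation and ≤ 4%
  passband deviation, comfortably within spec for both.
* an upper transition band much wider than the design order requires (e.g.
  8→10 Hz at 667 taps) is unconstrained by the exchange and admits anomalous
  response spikes (observed |H| > 1e5 near 9 Hz). `design_bandpass`
  validates the realized response over the full grid and rejects any design
  whose magnitude anywhere exceeds 1 + 2.5·ripple.

Zero-phase application means filtering introduces no delay, so the
cross-correlation lag between filtered PPG and ABP reflects only the
physiological/equipment offset.

**Windowing and artifact screening.** Records are cut into 350-sample
windows with 100-sample overlap (stride 250). A rule-based screen rejects
windows with: constant runs longer than 0.5 s in either channel
(flat-line), ABP outside 20–300 mmHg, PPG constant runs longer than 0.25 s
(sensor rail), or non-finite samples. The screen sits behind a pluggable
detector interface (any callable `pair -> (accept, reason)`), so a learned
artifact classifier can replace it without touching the pipeline.

**Phase matching.** The per-window lag is the argmax over lags in
[−125, +125] samples of the cross-correlation between the windows,
normalized per lag over the overlap region (a per-lag Pearson coefficient).
The normalization matters: the plain running-sum cross-correlation shrinks
with overlap length, and for smooth, oversampled pulse signals the cost of
losing one overlap sample is smaller than the cost of a one-sample
misalignment — biasing the plain argmax toward zero lag by one to two
samples. The per-lag normalized form recovers constructed shifts in
[−50, 50] exactly at zero noise. Exact ties break toward the smallest
|lag|. Sign convention: a positive lag is the number of samples the ABP
window must be shifted toward later time to align with the fixed PPG
window (ABP leads physiologically).

The aligned overlap of a 350-sample pair has 350 − |lag| samples; both
channels keep the first 256 of it (deterministic, order-preserving), and
pairs with overlap below 256 (|lag| > 94) are rejected with a length
reason. Per-record bookkeeping guarantees kept + rejected = extracted at
every stage.

**Normalization.** Min–max normalization maps each modality's global
minimum/maximum over the training-split windows to [0, 1]; the ABP min/max
are saved and de-normalize network outputs back to mmHg. The statistics are
deliberately fitted on the training split only and frozen — computing them
over all windows would leak test-set range information into both the inputs
and the inverse transform.

## Network

A 1-D U-Net maps a normalized 256-sample PPG window to a normalized
256-sample ABP window. Default configuration: depth 4, base 64 channels,
length-3 convolutions, 2× max-pooling, leaky-ReLU (negative slope 0.3),
dropout 0.5 after the deepest contraction block and after the bottleneck,
nearest-neighbour ×2 upsampling followed by a length-2 convolution
(a zero-insertion mode equivalent to a stride-2 transposed convolution is
config-selectable), skip concatenation at every resolution, and a linear
head 64→64→1. All convolutions use "same" padding, so every level
preserves temporal length and skip tensors concatenate without cropping;
the input length must be divisible by 2^depth (256 = 16·2^4). Channel
schedule: 64-128-256-512 down, 1024 at the bottleneck, mirrored up
(10.8 M parameters).

The output is linear, not squashed: targets are min–max normalized but
predictions may legitimately exceed [0, 1] for pressures outside the
training range.

The network, its backward pass, and the Adam optimizer are implemented
directly on numpy arrays (im2col convolutions as single GEMMs, float32
throughout). Gradients were verified against central finite differences in
directional-derivative form (relative error ~1e-3 at the kink-free scale
for this nonsmooth model, ~1e-5 for purely linear configurations).

## Training protocol

Subject-level 70/15/15 train/validation/test split (largest-remainder
apportionment of subject counts, seeded permutation; every split is
guaranteed at least one subject when three or more exist). Subject-level
splitting is the strict reading of "completely separated" data and prevents
within-subject leakage; window-level splitting remains available as a
config switch. Adam with learning rate 1e-4, batch size 4, MSE loss on
normalized windows, per-epoch reshuffling with the run seed, incomplete
final batch kept. Early stopping: an epoch counts as an improvement when
validation loss drops by more than 1e-6; after 5 consecutive
non-improvements training halts and the best-validation-epoch weights are
restored. `max_epochs` defaults to 100 in `TrainConfig`; the end-to-end
synthetic check caps it at 30, within which early stopping fires for the
default cohort (best epoch ≈ 22).

## Synthetic data generator

Each synthetic beat is a sum of two Gaussian lobes on a per-beat phase
grid — a systolic lobe at 30% of the beat and a smaller dicrotic (reflected)
lobe on the downstroke — and each beat is min–max rescaled so its sampled
maximum equals the record's SBP target and its minimum the DBP target
exactly (before additive noise). Beat periods are the nominal heart period
times `1 + U(−j, +j)` with j = 0.04 by default. The PPG is the same pulse
train convolved with a 0.1 s Hann kernel (the peripheral volume pulse is
rounder than the pressure pulse), delayed by the transit lag, min–max
scaled to [0, 1] arbitrary units, plus optional sub-0.5 Hz sinusoidal
baseline wander and white noise. ABP leads PPG: the brachial pressure wave
arrives before the fingertip volume wave.

Two generator properties carry the scientific weight:

* **Morphology encodes pressure.** Dicrotic amplitude (0.08–0.17 of pulse
  height), dicrotic timing (phase 0.70→0.54), and systolic width vary
  monotonically with mean pressure and pulse pressure. This is the working
  premise of cuffless PPG-based BP estimation — stiffer, higher-pressure
  arteries return the reflected wave earlier and larger — and it is what
  makes the absolute pressure level of a window identifiable from shape
  alone. Without it (PPG is unit-scaled per record, and the band-pass
  removes level information), no estimator could beat predicting the cohort
  mean. The dicrotic amplitude is kept below the 25% peak-detection
  prominence threshold so SBP/DBP extraction sees exactly one peak and one
  valley per beat.
* **Beat-to-beat variability.** The dicrotic lobe's size (±25%) and timing
  (±0.04 phase) vary per beat, shared between ABP and PPG. Quasi-periodic
  signals otherwise admit near-equal cross-correlation peaks one heart
  period away from the true lag; the shared variability makes the true
  alignment unique. With the band-pass applied, lag recovery on synthetic
  pairs is exact for lags in [0, 50] at noise SD ≤ 0.02 and ≥ ~99% exact at
  0.05 (residual misses are single-sample or one-period errors on the
  noisiest windows; the filter warm-up window at a record's very start can
  also alias by one period).

Artifacts are injected as ABP flat-lines or PPG rail saturation of 0.5–2 s,
at an expected rate of `artifact_rate` per extracted window, and recorded in
the ground truth.

What the generator does **not** emulate: real PPG nonstationarity (sensor
pressure, perfusion, skin tone), respiratory modulation of pulse amplitude,
arrhythmias, measurement drift in the invasive line, or any
patient-specific calibration error. Passing the synthetic end-to-end check
therefore demonstrates that the pipeline's machinery — filtering, alignment,
normalization, network capacity, optimization, extraction, and scoring — is
correct and identifiable under a faithful signal model; it does not
establish clinical accuracy on real recordings.

## BP extraction and evaluation

Per window: SBP = mean of detected systolic peak amplitudes, DBP = mean of
detected valley amplitudes, MAP = arithmetic mean of all 256 samples.
Peaks/valleys come from scipy's prominence-based detector with minimum
separation 0.27 s (≈220 bpm ceiling) and prominence 25% of the window's
peak-to-peak amplitude (suppresses dicrotic bumps); both are configurable.
Windows with no detected extrema are excluded from SBP/DBP aggregates but
retained for MAP, and counted in the report.

BP ranges follow the JNC7 cut-offs, most severe trigger winning: stage-2 at
SBP ≥ 160 or DBP ≥ 100; stage-1 at SBP ≥ 140 or DBP ≥ 90; pre-hypertension
at SBP ≥ 120 or DBP ≥ 80; otherwise normal.

Evaluation statistics, with their deliberate disambiguations:

* `error_stats` reports MAE, the standard deviation of **absolute** errors
  (the "MAE ± STD" presentation convention; sample SD, ddof = 1), RMSE, and
  Pearson r.
* `aami_check` computes the **signed** mean difference and its SD (the
  quantities the AAMI bound actually constrains: |mean| ≤ 5 mmHg and
  SD ≤ 8 mmHg) and can be switched to absolute errors for comparison with
  tables that list MAE against the same bound. It reports the > 85-subject
  condition separately from the mmHg verdict.
* waveform agreement is the per-window Pearson correlation between
  predicted and reference ABP, averaged through the Fisher-Z transform
  (tanh of the mean of atanh), with min/max and 25th/75th percentiles
  (linear interpolation) on the raw values; inputs at |r| = 1 are clipped
  to 1 − 1e-12 and counted.
* BHS grading uses inclusive thresholds (≤ 5/10/15 mmHg) against the
  60/85/95 (A), 50/75/90 (B), 40/65/85 (C) grid; the grade is the best row
  fully met, else D.
* Bland–Altman pairs plot (pred + ref)/2 against pred − ref with differences
  clipped to ±30 mmHg for display; bias and 1.96-SD limits of agreement are
  computed on unclipped differences.
* per-range accuracy groups windows by the **reference** label and reports
  both readings of a "prediction rate": the fraction of windows within
  10 mmHg per measurand, and the 4×4 range-confusion matrix.

## Problem sizes and split modes

The end-to-end synthetic check trains the full-size network (depth 4, base
64) on 20 subjects × 120 s (≈ 1,100 kept windows) for at most 30 epochs
with the protocol defaults above and a *window-level* 70/15/15 split — the
pooled-data reading of the reference protocol. Under that protocol the
pipeline reaches waveform avg r ≈ 0.98 and SBP/DBP MAE ≈ 5/4 mmHg on the
held-out windows.

Subject-level splitting (the stricter default elsewhere in the package)
makes the same run a cross-subject generalization problem with only 14
training subjects for the morphology→pressure map; there the per-subject
level calibration error dominates (SBP MAE ~8–15 mmHg depending on the
epoch early stopping selects), and the 3-subject validation split makes
patience-5 early stopping fire on noise well before training converges.
That is a data-scale limit of the cohort, not a pipeline defect; window
mode removes it by letting every subject contribute windows to training,
at the price of within-subject leakage — the same price the pooled
protocol pays on real data.

Smaller configurations (depth 2, base 8, 64-sample windows) are used in
unit tests and examples where only the machinery, not the capacity, is
under test.

## Known limitations

* The paper-scale result (hundreds of hours of ICU data, avg r ≈ 0.99,
  grade-A BHS) is out of reach of a synthetic desk-scale run and is not
  claimed; the synthetic check gates machinery, not clinical performance.
* Lag estimation can alias by one heart period for windows inside the
  filter warm-up region or at noise SD ≥ 0.05; such windows either trim
  harmlessly or are rejected for length.
* The numpy training loop is single-threaded and CPU-bound; it is adequate
  for the test-bed but not for dataset-scale experiments.
* WFDB ingestion requires the optional `wfdb` package; CSV and NPZ paths
  are self-contained.
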