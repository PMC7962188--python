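# wavebp

Continuous, non-invasive arterial blood pressure (ABP) waveform estimation
from a fingertip photoplethysmogram (PPG), with the full
preprocessing-training-evaluation pipeline around it.

Invasive arterial lines give the gold-standard continuous ABP waveform but
are reserved for critical care; a fingertip PPG is cheap and ubiquitous.
Because the volume pulse at the finger is a delayed, reshaped image of the
pressure pulse, a signal-to-signal model can learn the mapping between them.
`wavebp` implements that approach end to end:

1. **Preprocess** — band-pass the PPG to 0.5–8 Hz with a zero-phase
   equiripple FIR filter (baseline wander below 0.5 Hz, high-frequency noise
   above 8 Hz); cut both channels into 350-sample windows at 125 Hz with
   100-sample overlap; reject artifact windows (flat-lines, sensor rails,
   non-physiological pressures); phase-match each pair by the maximum of the
   normalized cross-correlation (the brachial pressure wave leads the
   fingertip volume wave); trim aligned pairs to 256 samples (2.048 s);
   min–max normalize with Eq.-style affine maps whose ABP factors are saved
   for de-normalization:
   `x_norm = (x - x_min) / (x_max - x_min)`.
2. **Model** — a 1-D U-Net (depth 4, base 64 channels, ~10.8 M parameters)
   maps a normalized 256-sample PPG window to a normalized 256-sample ABP
   window: two length-3 convolutions + leaky ReLU per block, 2× max-pooling
   down, 2× upsampling + length-2 convolution and skip concatenation up,
   50% dropout at the deepest encoder block and bottleneck, linear head.
   Implemented directly in numpy (im2col GEMM convolutions with hand-written
   backward passes and Adam), so the package has no deep-learning framework
   dependency.
3. **Train** — subject-level 70/15/15 split, Adam (lr 1e-4), MSE, batch 4,
   early stopping after 5 epochs without validation improvement, best-epoch
   weight restoration.
4. **Extract & evaluate** — per-window SBP (mean of systolic peaks), DBP
   (mean of diastolic valleys), MAP (window mean); JNC7 range
   classification; MAE/STD/RMSE/Pearson-r; Fisher-Z-averaged waveform
   correlation with percentiles; BHS cumulative-error grading; the AAMI
   mean ≤ 5 / SD ≤ 8 mmHg bound; Bland–Altman pairs (±30 mmHg display
   clip); per-range accuracy and confusion.

A synthetic-data module generates paired PPG/ABP records with known
per-beat pressures, transit lag, noise, baseline wander and artifacts, and
with pulse morphology that varies monotonically with pressure (the premise
of cuffless estimation), so the whole pipeline is testable without any
data download. See `docs/methods.md` for the model and every numerical
choice.

## Worked example

`examples/03_train_and_predict.py` trains a reduced network (depth 2,
64-sample windows) on six synthetic subjects and evaluates on held-out
subjects:

```text
stopped after epoch 4 (best epoch 1, max-epochs)
validation loss per epoch: [0.0096, 0.0185, 0.0318, 0.039]
test windows: 22
waveform correlation on held-out subjects: avg r = 0.864 (25th pct 0.528)
MAP:  MAE 7.56 mmHg, r 0.990
```

`avg r` is the Fisher-Z average of per-window Pearson correlations between
predicted and reference ABP waveforms — the shape-agreement number; MAP MAE
is the absolute error of the window-mean pressure in mmHg. The reduced
model already tracks waveform shape; absolute pressure accuracy needs the
full-size network (see the end-to-end test, which requires avg r ≥ 0.90,
SBP MAE ≤ 8 mmHg and DBP MAE ≤ 6 mmHg on 20 subjects × 120 s).

The other examples show the generator's guarantees
(`01_simulate_and_inspect.py`), the preprocessing bookkeeping
(`02_preprocess_windows.py`), and the evaluation statistics on a worked
numeric case (`04_evaluation_metrics.py`).

## Command line

```bash
wavebp simulate --n-subjects 4 --duration 120 --seed 1 --out-dir recs/
wavebp preprocess --in-dir recs/ --out windows.npz
wavebp train --data windows.npz --out model.npz
wavebp predict --checkpoint model.npz --record recs/subj-000.csv --out pred.csv
wavebp run-all --seed 1 --out run/
```

`run-all` executes the whole pipeline on a synthetic cohort and writes the
records, window dataset, checkpoint, evaluation report and a manifest with
per-stage window counts under the output directory.

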