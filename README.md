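# apneakit

Sleep-apnea screening from a single-lead ECG, for signal-processing and
sleep-medicine researchers who want a self-contained, inspectable
implementation of the per-minute deep-learning approach: no QRS detection,
no RR-interval analysis, no feature engineering — just a bandpass filter,
a z-score, and a 1D convolutional classifier over raw 1-minute ECG
windows.

## What it computes

**Per-minute classification.** Each 1-minute window (6000 samples at
100 Hz) is conditioned and classified as normal (`N`) or apneic (`A`):

- bandpass: a 4-pole digital Butterworth filter with a 0.5–15 Hz passband,
  applied as the causal recurrence
  `y(n) = Σₖ bₖ x(n−k) − Σₖ aₖ y(n−k)` with zero initial conditions
  (at 100 Hz the numerator is `b₀·[1, 0, −2, 0, 1]` with `b₀ = 0.1242`);
- standardization: `z = (x − μ)/σ` per window;
- classification: a 1D CNN of `d` identical feature-extraction blocks
  (conv 45×32 'same' → batch norm → ReLU → max-pool 2 → dropout 0.5),
  a flatten, 4 classification blocks (FC-512 → batch norm → ReLU →
  dropout 0.5) and a 2-unit softmax head.  At the reference depth
  `d = 10` the flattened feature vector has 5·45 = 225 entries and the
  network holds 1,499,788 parameters (≈1.5 M).

Training minimizes cross-entropy with Adam (batch 10, 50 epochs), repeats
the experiment over independent seeds and keeps the checkpoint with the
best validation accuracy.  The whole network is implemented in numpy with
explicit forward/backward passes, so every gradient is testable against
numerical differentiation.

**Per-recording screening.**  With `L` minutes in a recording and `N` of
them predicted apneic, the apnea–hypopnea index is estimated as

```
AHI = 60·N / L        (events per hour)
```

and a recording with `AHI ≥ 5` (inclusive) is called OSA.  Cohort
summaries report recording-level accuracy/sensitivity/specificity and the
Pearson correlation of estimated versus reference AHI — both against the
PSG-style reference value and against the AHI implied by the per-minute
annotations, which the literature sometimes conflates.

**Synthetic cohorts.**  `apneakit.synthetic` generates labelled ECG-like
recordings — Ricker-wavelet beat trains with sub-0.5 Hz baseline wander
and broadband noise, where apneic minutes carry the cyclic
bradycardia–tachycardia heart-rate swing that apnea imprints on the ECG —
so the entire pipeline is exercisable end-to-end without any download.
Recordings read and write in a WFDB-compatible layout (`.hea`/`.dat`
format 16 plus MIT-format `.apn` annotations), the same conventions as
the PhysioNet Apnea-ECG database, with a plain-CSV fallback.

## Worked example

`examples/04_train_and_screen.py` trains a scaled-down model (4 feature
blocks of 16 filters) on four synthetic recordings and screens two
held-out ones:

```
best validation accuracy 1.000 at epoch 22 of 25
held-out per-minute: accuracy 100.0%, sensitivity 100.0%, specificity 100.0%, AUC 1.000
syn05: estimated AHI 42.0 vs planted 42.0 -> OSA
syn06: estimated AHI 0.0 vs planted 0.0 -> non-OSA
recording-level agreement: accuracy 100.0%, Pearson r vs planted AHI 1.000
```

The first line is the best per-minute validation accuracy during
training; the AHI lines compare the index estimated from predicted
minutes with the cohort's planted truth, and the OSA calls apply the
inclusive `AHI ≥ 5` rule.  Perfect scores are expected here: the
synthetic classes are separable by design (see `docs/methods.md` for what
that does and does not demonstrate).  The other examples print the filter
design (`01`), the architecture shape/parameter table (`02`) and the
cohort's planted structure (`03`).

A command-line pipeline wraps the same calls:

```
apneakit simulate   --n-records 8 --minutes 60 --seed 0 --out-dir cohort/
apneakit preprocess --in-dir cohort/ --out segments.npz
apneakit train      --segments segments.npz --out-dir run/
apneakit evaluate   --checkpoint run/best --segments segments.npz --out-dir eval/
apneakit diagnose   --predictions eval/predictions.csv --truth cohort/truth.csv --out-dir diag/
apneakit sweep      --segments segments.npz --layers 1,2,3 --out-dir sweep/
```

Every command writes a `manifest.json` (config, seeds, versions, input
hashes, outputs) so runs are reproducible.  The reader also accepts real
Apnea-ECG records for full-scale experiments on that database.

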