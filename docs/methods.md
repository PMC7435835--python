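# Methods

## The detection problem

Obstructive sleep apnea (OSA) is conventionally diagnosed with overnight
polysomnography, which is expensive and inconvenient; a recurring research
goal is to pre-screen patients from a single-lead ECG alone.  The approach
implemented here classifies each 1-minute ECG window as normal (N) or
apneic (A) directly from the raw waveform, then aggregates the per-minute
calls into an apnea–hypopnea index (AHI) per recording and a binary OSA
call.  The premise is physiological: apnea episodes imprint a cyclic
bradycardia–tachycardia oscillation (and subtler morphology changes) on
the ECG, which a convolutional network can learn without explicit QRS
detection or RR-interval features.

## Preprocessing

Each minute (6000 samples at 100 Hz) is processed independently:

1. **Bandpass filter.**  A digital Butterworth bandpass with a 0.5–15 Hz
   passband, designed by the bilinear transform from an order-2 lowpass
   prototype, giving a 4-pole transfer function.  "Fourth-order" here
   means a degree-4 denominator: the filter's published difference
   equation has exactly four feedback terms, which an 8-pole textbook
   order-4 bandpass could not produce.  Filtering is causal
   (direct-form recurrence, zero initial conditions) and per-minute, so
   minute boundaries carry a small onset transient; this is accepted
   as-is because segments are windows, not a continuous stream.  The
   passband suppresses baseline wander (gain 0.0376 at 0.1 Hz, 0.0094 at
   0.05 Hz) while passing QRS energy.
2. **z-score.**  `z = (x − μ)/σ` with the *population* standard deviation
   (divide by n).  The convention is irrelevant at n = 6000
   (ratio √(6000/5999)) but is fixed for bit-reproducibility.  A
   zero-variance (flat-line) minute standardizes to zeros and emits a
   warning instead of raising, so one corrupt minute cannot abort a
   whole-recording run.

## Network and training

The classifier is a stack of `d` identical feature-extraction blocks —
conv(45 filters, kernel 32, stride 1, 'same' padding) → batch
normalization → ReLU → max-pool(2, stride 2) → dropout(0.5) — followed by
flatten, 4 classification blocks (FC-512 → batch norm → ReLU →
dropout(0.5)) and a 2-unit softmax head.  The reference depth is d = 10
(flatten width 225, 1,499,788 parameters); depths 1–12 are supported for
depth sweeps, limited only by the input length surviving `d` halvings.

Implementation choices, all recorded in `ModelConfig`:

- **Pooling** uses floor division; this is forced by the reference shape
  chain (…→ 23 → 11 → 5).
- **Batch normalization** uses momentum 0.99 and ε = 1e−3 (Keras-era
  defaults); the parameter count includes the moving mean/variance
  (4 per channel), which is what makes the total round to 1.5 M; the
  trainable-only count (1,494,792) is exposed separately.
- **He-normal initialization** draws from N(0, √(2/fan_in)) (plain, not
  truncated, normal — the truncation changes the variance by ~5% and
  nothing downstream depends on it), seeded explicitly.
- **Dropout** is inverted (scaling by 1/keep at train time), inactive at
  inference, so a trained model is deterministic per segment.
- **Convolution** is computed as a loop over kernel taps, each tap a
  strided BLAS matmul against a shifted view of the padded input; the
  backward pass for the input gradient is the transposed convolution.
  This avoids the 32-fold im2col memory blow-up and keeps single-CPU
  training practical.  All gradients are validated against numerical
  differentiation in the test suite.
- **Training**: categorical cross-entropy, Adam (lr 1e−3, β₁ 0.9,
  β₂ 0.999, ε 1e−7), batch size 10, 50 epochs by default.  Per-epoch
  training metrics are batch-averaged; validation metrics are a full
  inference pass at epoch end (hence smoother training than validation
  curves).  No class weighting, resampling, early stopping or schedules.
  The experiment repeats over independent seeds (10 by default) and the
  kept checkpoint is the epoch/experiment with the highest validation
  accuracy — never the loss; ties go to the earlier epoch and lower
  experiment index.

Hard per-minute predictions take the class with the greater probability;
an exact tie (p = 0.5) predicts N, so the positive call always requires
positive evidence.

## Per-recording screening

`AHI = 60·N/L` events/hour from L minutes with N predicted apneic; a
recording is called OSA iff AHI ≥ 5 (inclusive, following the AASM
definition).  Cohort summaries report recording-level
accuracy/sensitivity/specificity (OSA positive, percentages rounded
half-up to one decimal, matching hand-reported tables) and two Pearson
correlations: estimated AHI against the PSG-style reference value, and
against the AHI implied by the per-minute annotations.  Both are labelled
because published comparisons conflate the two definitions, which differ
substantially on the same predictions.

## Synthetic cohorts

The generator produces what the pipeline assumes and nothing more:

- beats are Ricker wavelets (width 3 samples ≈ 0.1 s QRS, spectral peak
  ~7 Hz, inside the passband) placed at the instantaneous heart rate,
  base 70 bpm with per-beat Gaussian jitter (sd 1.5 bpm);
- apneic minutes add a sinusoidal rate swing of 20 bpm at a 60 s period
  (configurable within the physiological 25–100 s range) with random
  phase — the cyclical variation apnea induces;
- baseline wander: a 0.1 Hz sinusoid at twice the beat amplitude (the
  slow respiratory/motion drift band, far enough below the 0.5 Hz edge
  that the filter removes ~96% of it);
- broadband Gaussian noise at 5% of beat amplitude.

The standard cohort is 8 records × 60 minutes; half the records are
"cases" whose apneic-minute rate is set so the cohort-wide prevalence is
0.35 (cases ≈ 0.68, controls 0.02), giving reference AHIs that span
clearly-OSA and clearly-control truth.  Reference AHI is computed from
the planted labels via 60·N/L.  Generation is fully deterministic given
the seed.  A built-in QC statistic (standard deviation of detected
inter-beat intervals per minute) must separate the planted classes with
AUC > 0.9 — the generator is only considered healthy if the learning
problem it poses is solvable.

What the generator does **not** emulate: P/T-wave morphology, EDR
amplitude modulation (off by default), arrhythmias, electrode artifacts,
apnea-hypopnea distinctions, or inter-patient variability in morphology.
Consequently, perfect accuracy on synthetic cohorts demonstrates that the
pipeline is wired correctly and that the model can learn heart-rate
dynamics from raw waveforms — it says nothing about accuracy on clinical
recordings, where reported per-minute accuracies are in the high 80s.

## Desk-scale configuration

CPU-bound experiments (tests, examples) use `ModelConfig.reduced()`:
4 feature blocks of 16 filters and 2 classification blocks of 128 units
(~0.8 M parameters), trained for ~12–25 epochs on the standard synthetic
cohort split by whole recordings (6 train / 2 held out).  At these sizes
a full train-and-score run takes about two minutes on one core and
reliably reaches 100% held-out per-minute accuracy across seeds; the
paper-scale 10-layer configuration remains the default `ModelConfig()`
and is exercised for arithmetic, instantiation and inference in the
tests.

## I/O conventions and edge cases

- WFDB subset: format-16 `.dat` (16-bit little-endian, gain in adu/mV),
  two-line `.hea`, MIT-format `.apn` annotations (codes 1 = N, 8 = A,
  SKIP pseudo-annotations for the 6000-sample minute intervals).  Only
  single-signal records; other formats are rejected with explicit
  errors.  A CSV fallback (one sample per line + one label per line)
  covers binary-averse environments.
- Labels outside {N, A} are rejected, never coerced.
- Label i covers samples [i·60·fs, (i+1)·60·fs), half-open and 0-based;
  a trailing partial minute is discarded; if annotation count and signal
  length disagree, both are truncated to the shorter.
- A sampling rate other than 100 Hz warns and proceeds without
  resampling (resampling is deliberately out of scope).

## Known limitations

- The published difference-equation coefficients are printed to 4
  decimals; iterating that rounded recurrence drifts from the exact
  design by up to ~3e−3 over 100 samples (the poles sit near the unit
  circle), so exactness checks compare the recurrence at full precision
  and the printed values at their printed precision.
- The numpy engine targets clarity and testability over speed: it is
  single-threaded BLAS-bound and roughly two orders of magnitude slower
  than a GPU framework, which is why full-database (70-recording,
  50-epoch, 10-repeat) reproduction is a long offline run rather than a
  test.
- No artifact rejection, powerline notch, multi-lead support or severity
  grading beyond the binary OSA call.
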