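# Methods

## Problem and scope

`forceskill` classifies a surgical trial as performed by an **Expert** or a
**Novice** from a univariate tool–tissue force trace (newtons, one sample
per time step, variable length). The package provides the whole benchmark
pipeline — preprocessing, a synthetic cohort generator, six training-time
augmentations, six sequence classifiers, two cross-validation schemes with
standard binary-classification metrics, and a temporal saliency overlay.
Time is treated as unitless steps throughout: the sampling rate of the
sensorized glove that motivates the data model is not part of the data
contract, and no operation depends on it.

## Preprocessing

1. **Negative clipping.** Piezoresistive force sensors can report small
   negative values when unloaded; every sample below 0 N is replaced by 0.
   The operation is idempotent and rejects non-finite samples, naming the
   first offending index.
2. **Standard scaling.** Mean and standard deviation are pooled over *all
   samples of all training-fold trials* (population convention, divide by
   N) and applied to training and test trials alike. Fitting on training
   folds only avoids test-set leakage; a per-trial mode
   (`TrainConfig.scaler_scope="per_trial"`) exists for sensitivity checks.
   Constant pooled data raises an error rather than producing a degenerate
   scaler.
3. **Crop or pad (training only).** Each training trial contributes one
   fresh random 300-step contiguous crop per epoch; shorter trials are
   zero-padded *after* the signal. Test trials are always evaluated at
   their original length. Trailing (rather than leading) padding is what
   makes the recurrent readout convention below necessary.

## Synthetic cohort generator

The generator exists so that every downstream module is testable without
any real recordings. A trace is

```
clip_[0,10]( moving_average( base + Σ triangular bursts + tremor ) )
```

with burst onsets a Poisson process (`burst_rate` per 100 steps), burst
peaks `Normal(burst_amp_mean, burst_amp_sd)`, burst widths `Uniform(5, 25)`
steps, tremor i.i.d. `Normal(0, tremor_sd)`, and a centered moving average
of half-width `smoothness`. Forces are clipped to the 0–10 N sensor range.

Default profiles encode the established clinical observation that novices
exert higher and more variable forces: expert = (base 1.0 N, 1.5 bursts/100
steps, peaks 1.5 ± 0.5 N, smoothness 4, tremor 0.15 N), novice = (base
2.0 N, 3 bursts/100 steps, peaks 4.0 ± 1.5 N, smoothness 1, tremor 0.5 N).
These values were chosen once, to give clearly separable classes (a
single threshold on per-trial mean force already classifies nearly all
trials — the acceptance script reports the exact baseline), and are not
tuning knobs.

The default cohort shape mirrors the motivating study: 7 experts + 6
novices, 16–20 trials each (~230 trials), trial lengths uniform on
100–600 steps. Each surgeon draws one multiplicative log-normal offset
(sd 0.15) on the burst amplitude, so surgeons differ systematically; this
inter-surgeon variability is what makes leave-one-user-out genuinely
harder than a random split. Trial-length uniformity and the specific burst
shape are modeling conveniences — the generator reproduces first-order
class structure (level, variability, spikiness), not the mechanics of
grape dissection, sensor drift, disconnection artifacts, or left-censored
trial durations. Passing tests on synthetic cohorts therefore demonstrate
that the pipeline is correct and can recover a known class signal, not
that any architecture attains a particular accuracy on real recordings.

## Augmentations

Six operators, all pure functions of (input, parameters, seed), applied to
training crops only, one named operator per experiment:

| name | effect | defaults |
|---|---|---|
| `fft` | stacks the signal with the real and imaginary parts of its one-sided DFT, zero-padded to T → 3×T input | deterministic |
| `quantize` | snap samples to the nearest of 10 equally spaced levels spanning the trace's own min–max; ties to the lower level | p = 0.5 |
| `drift` | multiply by a cubic spline through 5 random interior anchors with factors Uniform(1.1, 1.5), endpoints pinned at 1 | p = 0.5 |
| `timewarp` | double the speed inside 5 disjoint segments of ⌊T/20⌋ steps (keep every second sample), then linearly resample back to T | p = 0.5 |
| `gaussian_noise` | add i.i.d. Normal(0, 0.1) | always |
| `temporal_jitter` | shuffle 30 consecutive segments of 10 steps | always |

Choices that were genuinely open and are pinned here: the DFT rows are
zero-padded to T so one architecture input shape serves all augmentations
(the channel count, 1 or 3, is a build parameter); quantization levels are
anchored per-trace; drift is multiplicative (factors 1.1–1.5); the warp
segment length ⌊T/20⌋ guarantees five disjoint segments fit, and
resampling back to T keeps fixed-shape batches. Models trained with `fft`
apply the same transform to test inputs, since it is a deterministic
re-representation rather than a perturbation.

## Architectures

All six models end in a single logit with a sigmoid, trained with binary
cross-entropy (equivalent to a two-way softmax with categorical
cross-entropy). They run on a small numpy reverse-mode autodiff backend
inside the package (`forceskill.nn`); every fused backward pass (LSTM, GRU,
convolution, pooling, batch normalization, attention softmax) is verified
against central finite differences in the test suite.

* **lstm / gru** — 4 recurrent layers, hidden size 64, affine 64→1.
* **bilstm** — 4 bidirectional layers (64 per direction); readout
  concatenates the final forward and final backward states (128).
* **cldnn** — Conv1d(→64, k=5, same) + ReLU + MaxPool(2,2), Conv1d(→128,
  k=5, same) + ReLU + MaxPool(2,2), then 4 LSTM layers (hidden 64) over the
  T/4-step sequence, affine 64→64 + ReLU, affine 64→1. The convolution
  kernel (5) and pool (2, stride 2) are pinned; the architecture constraint
  is the halving T/2, T/4 of the two blocks.
* **tcn** — four blocks of Conv1d(k=25, stride 1, pad 12) → BatchNorm →
  ReLU → MaxPool(k=3, stride 1, pad 1), channels 64, 32, 16, 16; the
  temporal length is preserved end to end (non-dilated, non-causal); the
  final 16×T map is averaged over time and fed to affine 16→1.
* **transformer** — pointwise Conv1d to width 16, one 8-head self-attention
  block (head width 2, no positional encoding and no residual connection —
  a deliberately minimal reading), BatchNorm, temporal average, affine
  16→16 + ReLU, BatchNorm, affine 16→1.

Conventions that the data contract forces: with trailing zero padding, the
recurrent readout uses the hidden state at the last *non-padded* step (true
lengths are tracked through the pipeline; for CLDNN the valid length is
divided by 4 alongside the pooling). Batch-normalization layers use
accumulated running statistics at evaluation, so batch-size-1 evaluation on
full-length trials is well defined. The TCN block order conv → norm → ReLU
→ pool is pinned for test stability.

## Training and evaluation

`TrainConfig` defaults: 100 epochs, batch size 32, Adam at 1e-4, crop
length 300, validation fraction 0.15. Each epoch draws one fresh crop per
training trial. After every epoch the cross-entropy on a stratified
validation subset carved from the training folds is computed on full-length
sequences in evaluation mode; the parameters with minimum validation loss
are returned. Monitoring the test fold instead is available
(`select_on_test=True`) but off by default because it leaks. The decision
threshold on the sigmoid output is 0.5; Expert is the positive class.

**Folds.** The random split shuffles each surgeon's trials and deals them
round-robin (random starting fold per surgeon), so per-surgeon fold counts
differ by at most one. LOUO pairs each expert (group) with one novice in
roster order; when experts outnumber novices the caller merges experts —
`default_louo_merges` merges those with the fewest trials. The split
construction guarantees no surgeon appears on both sides of any fold.

**Metrics.** Accuracy, precision, recall, F1 from the confusion counts
with Expert positive. A metric with an empty denominator is reported as
undefined (`None`), never silently 0; cross-fold means skip undefined
entries with a warning. The "± " columns are sample standard deviations
over folds (ddof = 1).

**Determinism.** One master seed fixes cohort generation, fold assignment,
the train/validation carve, crops, augmentation draws and parameter
initialization; repeated runs reproduce the full report bit-identically.

## Saliency

For TCN and CLDNN the final pre-head feature map (TCN: fourth-block output,
16×T; CLDNN: the last recurrent layer's sequence output, 64×T/4 — the
fully-connected activations have no temporal axis, so the recurrent
sequence is the last temporally resolved feature) is averaged over the
feature axis, min-max normalized to [0, 1] (a constant map yields all
zeros: "no attention anywhere"), and linearly interpolated to the trial's
original length. TCN needs no interpolation because its temporal
resolution is preserved. The raw (not absolute) activations are averaged;
min-max normalization makes the track invariant to affine rescaling of the
activations. The overlay colors the force trace by intensity with a
cold-to-warm colormap and renders deterministically.

## Problem sizes used in the checks

The automated checks run scaled-down analogues of the benchmark: the
memorization check uses 16 perfectly separated trials with Adam at 1e-3
(a capacity check, not the benchmark recipe) and at most 30 epochs; the
synthetic-cohort benchmark uses the default ~230-trial cohort with 10
epochs for TCN and 25 for CLDNN — on the strongly separable synthetic
classes both models reach their plateau well within these budgets, and
validation-loss model selection keeps the best epoch regardless.

## Known limitations

* The synthetic generator is a first-order emulation; accuracies measured
  on it say nothing quantitative about real glove recordings.
* The transformer has no positional encoding or residual connections by
  design (minimal reading); it relies on the convolutional lift and
  attention mixing only.
* The numpy backend is single-threaded-CPU oriented; it is adequate for
  the cohort sizes here but not for large-scale training.
* Undefined-metric folds (e.g. a fold with no positive predictions) are
  skipped in cross-fold means, which can make means over few folds
  optimistic; the per-fold table always contains the full picture.
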