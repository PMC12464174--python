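# Methods

## Problem and pipeline

`seizurekit` classifies fixed-length EEG windows as seizure or background
(or into several seizure types).  The pipeline is:

1. **Ingestion** — single-channel plain-text segments (one sample per line,
   nominally 4097 samples at 173.61 Hz) or multi-channel 16-bit EDF
   recordings (256 Hz montages with 22+ channels).  Recordings can be
   truncated to their first k channels, band-limited-resampled to a common
   rate, and cut into non-overlapping (or overlapping) windows labelled
   from interval annotations.
2. **Normalization** — every window is z-scored per channel (zero mean,
   unit population variance).  The transform is stateless: it uses only the
   window itself, so no statistic is ever fitted on one fold and applied to
   another.
3. **Features** — each channel is decomposed with an L-level discrete
   wavelet transform (default: Haar/db1, level 3) and the coefficient
   arrays are concatenated coarse-to-fine, `[A_L, D_L, ..., D_1]`, then
   channel-major across channels into a single 1D vector.  At 256 Hz the
   level-3 bands nominally cover 0–16 Hz (A3), 16–32 Hz (D3), 32–64 Hz
   (D2) and 64–128 Hz (D1).
4. **Classifier** — a 1D CNN-LSTM over that vector treated as a
   length-N single-feature sequence: six valid-padding convolutions
   (16/32/64/128/256/512 filters), batch normalization and ReLU after each,
   four max-pools (size 3, stride 2), a single 200-unit LSTM whose final
   hidden state feeds a 64-unit L2-regularized dense layer, dropout 0.4 and
   a classification head — one sigmoid unit for binary problems, an
   n-class softmax otherwise.  For an input of length 4100 the stack totals
   765,553 parameters (the conv/pool length rule is
   `out = floor((in − k)/s) + 1` throughout).
5. **Evaluation** — stratified 10-fold cross-validation with an
   inverse-frequency class-weighted cross-entropy loss; seven
   confusion-matrix metrics (sensitivity, specificity, accuracy, PPV, NPV,
   MCC, F1) on the percent scale; rank-based ROC-AUC; fold-paired
   statistical comparison (paired t, Wilcoxon signed-rank, Cohen's d).

## Why db1 and level 3

The wavelet is configurable, but the default is db1 (Haar, filter length
2) at level 3: under the coefficient-length recursion
`len_next = floor((len + f − 1)/2)` a 4097-sample channel yields
513 + 513 + 1025 + 2049 = 4100 coefficients — exactly the reference
network's input length — whereas db3 (f = 6) would yield 4111.  Only the
filter length enters the length rule, so this identity pins the default
wavelet choice.

## Network engine

The network is implemented directly on NumPy: layers carry explicit
`forward`/`backward` passes (validated against central finite differences
to ~1e-8 relative in the test suite), optimized with Adam (β₁ 0.9,
β₂ 0.999, ε 1e-7).  Head activations are fused into the loss gradient
(`p − y` at the logits) for numerical stability.  Conventions chosen where
several are common:

* **Parameter accounting** counts batch-norm moving statistics, i.e. 4
  parameters per normalized channel (γ, β, moving mean, moving variance).
* **Batch normalization** uses ε = 1e-5 and momentum 0.99, with
  *bias-corrected* moving statistics: the exponential moving averages are
  divided by `1 − momentum^t` when read.  Without this correction a model
  trained for only a few dozen steps evaluates against statistics still
  dominated by their initialization (mean 0, variance 1) and inference
  output is meaningless; with it, small-budget synthetic experiments and
  long trainings use the same code path.  The correction changes nothing
  asymptotically.
* **LSTM** gates are ordered input/forget/cell/output with sigmoid gates
  and tanh cell, Glorot-uniform input kernels, orthogonal recurrent
  kernels, forget-gate bias 1; only the final hidden state is emitted.
* **Dense L2** follows the `λ · Σw²` convention (λ = 0.03 on the 64-unit
  layer).
* **Dropout** is inverted (scaling by 1/(1−rate) during training),
  identity at inference.
* The binary head is a single sigmoid unit thresholded at 0.5
  (configurable); multi-class heads take the argmax of the softmax.

## Training protocol

Per fold: 10% of windows held out for testing (stratified), then 15% of
the remaining 90% split off — again stratified — for validation, giving
76.5 / 13.5 / 10 proportions.  A fresh network is built per fold; data are
shuffled before training and re-shuffled every epoch; training runs a fixed
number of epochs (no early stopping).  Reference recipe: Adam at learning
rate 1e-4, batch size 60, 300 epochs, 10 folds.  Class weights are
`w_c = n_total / (n_classes · n_c)`, which reduces to 1 for balanced data.

Fold assignment, validation splitting, weight initialization, dropout masks
and epoch shuffling all derive from the config seed, so a run is
reproducible from its config snapshot alone (within floating-point
determinism of the BLAS in use).

## Synthetic data

The generator emulates the *shape* of the three dataset families the
pipeline targets (single-channel ~4097-sample text segments; long
multi-channel 256 Hz records; one-second 22-channel windows) and a
two-regime signal model:

* background — pink (1/f) noise plus an alpha-band (10 Hz) sinusoid;
* seizure — background plus a ~3 Hz spike-and-wave complex (half-width
  sawtooth wave with a sharp Gaussian spike each cycle) and a gamma-band
  (40 Hz) sinusoid.

Oscillatory phase is shared across channels with small per-channel jitter;
pink/white noise are independent per channel.  Per-record random streams
derive from one master seed via `SeedSequence(seed, spawn_key=(record,))`,
so any record is individually reproducible.  The regimes differ in the
delta/alpha and gamma bands — precisely the A3/D2 sub-bands of the level-3
decomposition — and class separability is controlled by the seizure
amplitude parameters relative to `noise_sd`.

What the generator does *not* emulate: physiological seizure morphology
and evolution, inter-subject variability, electrode artifacts (EMG/EOG),
line noise, or non-stationary background.  Tests passing on this surrogate
establish that the machinery is correct (shapes, training dynamics,
metric arithmetic, determinism), not that any particular accuracy carries
over to clinical recordings.

Default desk-scale study conditions used by the heavier tests, chosen once
as plausible synthetic regimes:

* *separable*: seizure gamma amplitude 2.0, spike-wave amplitude 3.0,
  noise SD 0.3 — the spectral classes are cleanly distinguishable (a KNN
  on the wavelet features exceeds 99%), so a correctly wired network must
  learn them;
* *noisy*: gamma 1.0, spike-wave 1.5, noise SD 1.0 — broadband noise of
  the same order as the discriminative components; class information is
  present but partial.

## Desk-scale profiles

Synthetic experiments run at a few hundred single-channel one-second
windows (256 samples; the conv/pool stack needs an input length of at
least ~248 to survive four pools) with 15–40 epochs and 3–5 folds; the
reference recipe (300 epochs, 10 folds) remains the config default.  With
only a few thousand optimizer steps the network reaches perfect accuracy
on the separable regime and clearly-above-chance accuracy on the noisy
regime, while label-shuffled data stays at chance.

## Numerical and degenerate-case conventions

* Constant (zero-variance, up to rounding of the mean) channels normalize
  to zeros, with a logged warning.
* DWT border extension is symmetric; it changes coefficient values but not
  lengths.  Orthogonal-wavelet energy conservation (Parseval) is exact
  only when no extension occurs, i.e. when every level's input length is
  even; energy tests therefore use dyadic lengths, where the identity
  holds to machine precision.  At odd lengths the duplicated boundary
  sample perturbs total energy by O(x²_border / E).
* Metrics with a zero denominator are reported as NaN with an explicit
  flag and excluded from macro averages (with a warning) — never silently
  zero.  Multi-class MCC is the per-class one-vs-rest value (macro
  averaged), not the multiclass generalization.
* Window labels come from majority annotation overlap; ties break toward
  the higher class index (toward "seizure" in binary problems — the
  safety-biased choice for a detector).
* Annotations are in seconds; sample indices are 0-based with half-open
  window intervals `[start, start + W)`, converted by `floor(t · fs)`.
* EDF channels with heterogeneous rates are resampled to the maximum rate
  on load.  The EDF writer quantizes linearly to 16 bits between the
  per-channel physical extrema; round-trip error is bounded by half a
  quantization step (span / 2¹⁶).
* `compare_models` flags zero-variance difference vectors as degenerate
  (Cohen's d undefined or ±∞); identical vectors report Wilcoxon p = 1 by
  convention.

## Ablations

Three minimal-surgery variants isolate component contributions:

* `no_dwt` — the unchanged network fed the raw normalized window
  (flattened channel-major) instead of wavelet coefficients;
* `no_lstm` — the LSTM removed; the final pool output (31 × 512 at input
  4100) is flattened straight into the dense head;
* `no_cnn` — the wavelet vector fed directly, as a (length, 1) sequence,
  to the 200-unit LSTM and then the dense head.

All three are trained on the same stratified folds as the full model at a
matched epoch budget.  On the noisy regime the expectation is directional
— the full model's mean CV accuracy should not fall below any variant's —
and is asserted with a 5-percentage-point tolerance on fold means, since
at desk scale single-seed mean differences of a few points are within
fold-to-fold noise (the no_dwt variant in particular can tie the full
model when the raw waveform already exposes the discriminative bands).

## Known limitations

* The network engine is CPU NumPy: fine for desk-scale studies and
  correctness work, not for training on full clinical corpora.
* No EDF+ annotation-channel parsing; annotations enter through the API or
  manifest files.
* The Welch features use a fixed `nperseg = min(256, n)`; very short
  windows (< 8 samples) are rejected rather than padded.
* Baseline hyperparameters are scikit-learn defaults, frozen for
  comparability rather than tuned.
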