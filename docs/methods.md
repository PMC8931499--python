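# Methods

This note documents the models, the synthetic benchmark, the numerical
choices and the known limitations of the package. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Problem setting

High-frequency oscillations (HFOs) are short (tens of milliseconds)
oscillatory bursts in the 80–500 Hz band of MEG/EEG recordings, used as
biomarkers of epileptogenic tissue. The detection task is binary
classification of fixed-length single-channel segments — default 2000
samples at 2400 Hz — into HFO (contains a burst) versus normal control (NC,
background only). Continuous recordings are handled by band-pass filtering
the whole signal, cutting stride-spaced windows, and classifying each
window.

A note on segment duration: a 2000-sample window at 2400 Hz spans ~0.83 s.
Segments are defined by sample count `T` (the shape the classifier
consumes); the sampling rate is carried in metadata and both are
configurable.

## Synthetic benchmark

The simulator emulates the statistical structure of an expert-marked gold
standard so that every stage is testable without data access:

* **Background**: spectrally shaped 1/f^α noise (α = 1 by default,
  synthesized by random-phase spectral shaping) plus white noise
  (relative SD 0.5). The mixture is rescaled by a deterministic,
  analytically derived factor so the *expected* 80–500 Hz band RMS is 1.0;
  individual segments keep their natural energy variability.
* **Events**: envelope-windowed sinusoids (Gaussian envelope,
  σ = duration/6, or Hann), center frequency in [80, 500] Hz with the
  four-cycle constraint `duration × frequency ≥ 4`, random phase, onset
  uniform over the segment interior. Default morphology: 150 Hz, 80 ms.
* **SNR convention**: an event's `amplitude` is its RMS over its own
  duration divided by the background in-band RMS (the usual RMS-ratio SNR).
  The benchmark condition is amplitude 3. Per-segment parameter jitter is
  multiplicative ±20% on frequency, duration and amplitude.
* **Datasets**: 101 + 101 segments by default, matching the size of a
  typical clinical gold standard. Determinism: every operation is
  bit-reproducible from its seed, and an HFO segment with amplitude 0 is
  sample-identical to the NC segment of the same seed.
* **Recordings**: multi-channel independent backgrounds with events summed
  in linearly at stated onsets; the ground-truth event list is stored and
  can be exported as a BED-like TSV.

What the simulator does **not** model: dipole/forward-field physics, sensor
geometry, cross-channel correlation, physiological artifacts, spikes
(an optional low-frequency transient component is exposed but off by
default, since the composition of real NC segments is not characterized).
Consequently, passing tests show that the pipeline detects band-limited
transient energy against 1/f-plus-white background at a stated SNR — not
that it reaches any particular accuracy on clinical recordings, where
classes may differ in additional (e.g. global spectral) ways.

## Preprocessing

Zero-phase 4th-order Butterworth band-pass (80–500 Hz), applied to the
*continuous* signal before windowing so window edges do not ring; this
ordering is pinned by a test. Default stride equals the window length
(non-overlapping); overlap is configurable.

Per-segment scaling before classification is **robust**: center by the
median, scale by 1.4826 × MAD. Rationale: after band-passing, a segment's
total variance *is* its in-band variance, so a plain z-score forces every
segment to unit band energy and erases exactly the cue that distinguishes a
burst-bearing window; the MAD is dominated by the background and therefore
preserves burst prominence, mirroring the background-RMS normalization of
classical envelope-threshold HFO detectors. A z-score mode remains
available (`normalize="zscore"`), as does raw pass-through.

## Classifier

Input framing (how a 1-D segment becomes a token sequence) is a design
choice of this package: `p = 20` consecutive samples per frame, linearly
projected to `d = 64`, giving 100 tokens for `T = 2000`; `h = 4` heads so
`d_k = d_v = 16`. No positional encoding is applied by default — the dense
head reads the tokens in order, so ordering information is not lost — and a
sinusoidal encoding is available behind a flag.

Each of the `N` stacked layers applies attention and feed-forward sublayers
wrapped as `Norm(ReLU(sublayer(x) + x))`. Placing the rectifier between the
residual sum and the normalization is nonstandard but is the package's
reference form; the conventional post-norm `Norm(x + sublayer(x))` is
available via `post_norm="standard"`. Attention scores are scaled by
`1/sqrt(d_k)` (the `attention_scale="linear"` flag gives `1/d_k`). The
feed-forward width defaults to `4d`. The head flattens the token matrix
(mean pooling behind `pool="mean"`) into dense layers of 128 and 10 ReLU
units and a single sigmoid unit.

Training: binary cross-entropy (probabilities clipped at 1e-7), RMSprop
(lr 1e-3, ρ = 0.9, ε = 1e-8), batch 32, 10 epochs, dropout 0.1 on the input
during training only. All weights are Glorot-uniform from the training
seed; shuffling, dropout masks and initialization share one generator, so
runs are exactly reproducible. Gradients are computed by hand-written
backpropagation (numpy only) and are verified against central finite
differences in the test suite. Float32 is used for training speed; the
gradient check runs in float64.

## Baselines

* **Logistic regression** operates on rectified amplitudes `|x|` of the
  conditioned segment. With burst phase and position uniformly random, the
  signed samples of the two classes have identical means, so *no* linear
  rule on raw samples can beat chance; the rectified band-limited amplitude
  is the classical linear representation for HFO energy detection. A raw
  mode (`features="raw"`) is provided. Because segments have far more
  dimensions than any realistic training set (perfect separability), the
  default keeps a mild ridge penalty (`C = 1`); `C=None` gives the pure
  maximum-likelihood fit.
* **Stacked sparse autoencoder (SSAE)**: three sigmoid hidden layers of 30
  units, greedily pre-trained with squared reconstruction error, L2 weight
  penalty and a KL-divergence pull of the mean hidden activation toward the
  sparsity proportion, then fine-tuned with a logistic output unit
  (lr 0.01). Fine-tuning stops early when the validation loss (20% split)
  is identical within 1e-9 for three consecutive epochs. Sparsity and L2
  weights are selectable from {0.1, …, 0.5} by validation accuracy.
* **Residual-dense variant**: the attention sublayer of every block is
  replaced by a position-wise dense ReLU map of width 128 (the width of the
  first head layer) projected back to `d`; depth semantics, wrappers, head
  and training are identical to the attention model.

### Why the residual-dense variant fails on this benchmark

On the synthetic task the *only* class difference is a localized burst at
an unknown position. Detecting it requires comparing token energies across
positions. Per-token layer normalization removes token amplitude after
every block, and a position-wise map has no mechanism to compare tokens —
whereas attention forms exactly such comparisons (query–key products)
before normalization strikes. Empirically the residual-dense model either
memorizes the training folds (flatten head) or collapses to a constant
predictor (mean pooling), and stays at chance on held-out folds across
frame widths, learning rates, pooling modes, both post-norm variants, and
single- versus two-dense replacements. We report this as a finding, not a
defect: it isolates multi-head attention as the operative ingredient of the
detector on pure event-detection data. On clinical gold standards the
classes plausibly differ in global, position-independent ways that a
position-wise network can exploit, which would explain the much smaller
attention-versus-dense gap reported there.

## Augmentation

ADASYN with Euclidean k-NN (k = 5, ties broken by lowest index): hardness
weight `r_i` = fraction of majority points among the combined-set k-NN of
minority sample `i`; normalized weights allocate per-sample quotas of the
requested synthetic count (rounded, then truncated/topped up by sampling
parents proportionally to the weights so the total is exact); each virtual
sample is `x_i + λ(x_z − x_i)`, `λ ~ U[0,1]`, with `x_z` a random minority
k-NN. If no minority sample has majority neighbors the weights fall back to
uniform with a warning. For balanced data the imbalance is manufactured
(three bins per class, rotating); the imbalance-threshold check is bypassed
there and `factor × n` virtual samples are produced, split equally by
class. A factor of 1 therefore doubles the training set, and factor 0 is a
no-op — distinct settings. Virtual samples carry provenance tags and are
excluded from every evaluation fold (asserted at run time).

Whether augmentation should be applied once globally or per training fold
is ambiguous in general; the default here is per-fold (leakage-safe), with
`global_augment=True` reproducing the riskier global variant (virtual
samples still never enter test folds).

## Evaluation

Positive class = HFO. Metrics: accuracy, precision, sensitivity,
specificity, and F-score (harmonic mean of precision and sensitivity);
zero denominators yield 0 with a `degenerate` flag and a warning rather
than an exception. Cross-validation is stratified with shuffling from the
seed; `k` defaults to 5; aggregate confusion counts are summed over folds
and metrics computed from the aggregate. The depth × factor sweep runs one
cross-validation per cell with deterministic seed offsets and writes a
tab-delimited table.

## Problem sizes

The test suite and the acceptance script use a full-size benchmark
(101 + 101 segments of 2000 samples, SNR 3, 5-fold, the attention model at
`N = 2`) for the end-to-end checks, and a reduced set (30 + 30 segments of
400 samples, 3-fold) for the depth × factor sweep (`N ∈ {1, 2, 10}`,
factors {0, 5}) and for unit-level training checks — sizes chosen so the
whole suite runs in a few minutes on one CPU while exercising every code
path at full dimensionality at least once.

## Known limitations

* The simulator is statistical, not biophysical (see above); absolute
  accuracies on it do not transfer to clinical data.
* The residual-dense baseline is at chance on the synthetic benchmark for
  the structural reasons given above.
* The SSAE detector is a faithful small-scale reimplementation of the
  described architecture but its hyperparameter-selection protocol
  (validation split and grids) is a package choice.
* EDF files can be read (via mne, optional extra) but not written;
  recordings persist in the package's npz container.
* `batch_size` counts segments; training data are treated as exchangeable
  segments, ignoring any patient-level grouping.
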