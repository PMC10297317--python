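# Methods

This note documents the models, algorithms and design choices behind
`tcdonn`: a pipeline that turns transcranial-Doppler (TCD) recordings of the
middle cerebral artery into maximal cerebral blood-flow-velocity (CBFV)
envelopes, and classifies fixed-length envelope windows as coming from
healthy subjects or critically ill ("ICU") patients with operational
(Self-ONN) residual networks.

## Operational convolutions (generative neurons)

A standard 1D convolutional neuron computes, for output channel *k* at
position *m*,

    x_k[m] = b_k + Σ_i Σ_r w_{k,i}[r] · y_i[m·s + r − p].

A *generative* neuron replaces the scalar tap weight with a length-*Q*
coefficient vector and feeds elementwise powers of the input through it:

    x_k[m] = b_k + Σ_i Σ_r Σ_{q=1..Q} w_{k,i}[r,q] · ( y_i[m·s + r − p] )^q,

a truncated Taylor series whose coefficients are learned, so each connection
learns its own nonlinearity.  `Q` controls the approximation order; at
`Q = 1` the layer is exactly a standard convolutional layer.  We use the
cross-correlation convention (no kernel flip) and zero padding, as in
mainstream deep-learning frameworks.

Because the Taylor expansion is only trustworthy near zero, the surrounding
architecture keeps layer inputs inside roughly [−1, 1]: the waveform input
is z-scored with training-set statistics and every operational layer is
followed by batch normalization and a `tanh` activation.  This is a
documented expectation, not a per-layer assertion.

Implementation: the input is expanded channel-wise into its powers
1..Q and convolved once with the flattened (C·Q)-channel kernel via
im2col + GEMM.  A deliberately naive quintuple-loop oracle
(`reference_selfonn_oracle`) implements the same sum with explicit loops and
is used in tests to validate the vectorized path (max abs difference
≤ 1e−5 over random instances).

**Initialization.** Weights are drawn uniformly in ±1/√(in_channels·K·Q)
with zero bias.  Including Q in the fan-in keeps the summed response of the
Q power terms at the magnitude of a plain convolution's response for inputs
in [−1, 1].

## Architectures

`Self-ResNet18` is the classic 18-weighted-layer residual topology with
operational layers in place of convolutions and `tanh` in place of ReLU:

- stem: operational layer, 8 filters, kernel 7, stride 2, then
  batch-norm + tanh (no max-pool — it would discard temporal resolution the
  1024-sample windows can afford to keep);
- four stages of two residual blocks with channel widths 8/16/32/64;
  each block is conv(k=3)–BN–tanh–conv(k=3)–BN, shortcut add, tanh;
- the first block of stages 2–4 downsamples with stride 2; its shortcut is
  a learned 1-tap operational projection *without* batch normalization;
- global average pooling over time, a linear layer to 2 outputs, and
  log-softmax.

That yields 17 operational layers plus the final dense layer — 18 weighted
layers on the main path, the canonical ResNet18 count — with the 3 shortcut
projections excluded from the count.

`Self-ResAttentioNet18` adds one multi-head attention layer (2 heads) to the
second, non-strided block of each stage (4 attention layers total).  Time
positions are the tokens and channels the embedding; the block's *input*
(identity features) provides query and value, the block's *output* the key;
the attended feature is added to the block output before the closing tanh.
Placing attention on non-strided blocks is the only placement where query
and key shapes agree without extra resampling.  The attention uses learned
square projections for query/key/value and a learned output projection; the
1/√d score scaling is folded into the query projection for speed.

Counting parameters, the layer inventory is invariant to Q; the Q = 3 build
carries exactly 3× the operational kernel weights of the Q = 1 build.

## The numerical engine

The networks run on a small reverse-mode automatic-differentiation engine
written on numpy (`tcdonn.nn`): broadcast arithmetic, batched matmul,
strided/padded 1D convolution (im2col + BLAS GEMM), elementwise integer
powers, tanh, softmax/log-softmax, batch normalization composed from
primitives, Adam, and a reduce-on-plateau schedule.  Default precision is
float32 (training is memory-bandwidth-bound); float64 is switchable for
verification, and every primitive's analytic gradient is checked against
central differences in the test suite.  Determinism follows from seeding
every random draw through `numpy.random.default_rng` and from numpy's own
run-to-run determinism.

## Envelope extraction

The Doppler-shift signal is short-time Fourier transformed (Hann window,
default 50 ms window / 10 ms hop; frames start at hop multiples with no
padding, so the frame count is floor((L − window)/hop) + 1).  Frequency
bins map to axial velocity by v = c·f_d/(2·f₀) with carrier
f₀ = 1.75 MHz, speed of sound c = 1540 m/s and insonation angle assumed 0°
(only the carrier is known; an uncorrected angle rescales velocities
without changing waveform shape).

The magnitude image is converted to dB (floored at −80 dB to avoid log 0)
and binarized with a global Otsu threshold; a constant image falls back to
its midpoint, which with a strict comparison yields an all-false mask.  The
binary image is despeckled with a 2D median filter whose kernel covers
0.03 s × 5 cm/s, converted to the nearest odd bin counts (minimum 1);
borders use replicate padding so median-stable regions are exactly
idempotent.

Per time frame the tracer takes the top of the highest run of true pixels
whose length is at least a configurable fraction (default 0.5) of the
column's true-pixel count — an adaptive acceptance that rejects thin
speckle remnants above the filled spectrum while keeping the spectrum body.
Two physiological sanity checks follow, in order: a range check (values
outside (0, 300] cm/s by default are invalidated) and a continuity check
(frame-to-frame jumps above 30 cm/s are replaced by the carried-forward
value and flagged invalid).  The trace is linearly resampled to 217 Hz and
the validity mask propagated (a resampled point is valid only if its
neighbouring frames are).  The tracer is validated by parameter recovery:
on synthetic filled spectra built from a known velocity curve it recovers
the curve with RMSE ≤ 2 velocity bins, and 0.1 % speckle leaves the error
unchanged to within one bin after despeckling.

## Segmentation and quality annotation

Envelopes are split at invalid samples into maximal valid runs; runs
shorter than 1024 samples are discarded.  Runs are cut into 1024-sample
windows at stride floor(1024·(1 − overlap)); 80 % overlap (stride 204) is
used as augmentation *for training data only* — validation and test windows
never overlap, so near-duplicate windows cannot straddle the evaluation
boundary.

Each window receives a quality label.  `rejected`: any NaN, any constant
("plane-line") run longer than 217 samples (≈1 s), or values outside
(0, 300] cm/s.  Otherwise cardiac periodicity is scored by the normalized
autocorrelation maximum in the 0.4–1.5 s lag band (40–150 bpm);
below 0.3 the window is `corrupted`, else `clear`.  Manual labels supplied
through the manifest always override the heuristic.  Corrupted windows are
kept for training by default (configurable); rejected windows never reach
the classifier.

## Session-independent cross-validation and training

Recording sessions — not segments — are the unit of splitting.  Per class,
sessions are shuffled deterministically and dealt into k = 5 disjoint,
size-balanced test groups; each fold trains on the remaining sessions with
roughly 10 % of training segments (whole sessions, smallest-first by deal
order) held out for validation.  A leakage guard re-verifies at run time
that no session appears on both sides of any fold boundary and that the
five test sets partition the sessions.

Training hyperparameters: Adam, learning rate 1e−4, batch size 4, up to
100 epochs (20 in the scaled-down reference experiment), loss
"SoftM_MSE" — the mean squared error between the softmax probabilities
(exponential of the log-softmax head) and the one-hot target, the only
reading of that loss name consistent with a log-softmax output layer.  For
two classes this loss lies in [0, 1] and vanishes only at an exactly
one-hot correct prediction.  The learning rate is multiplied by 0.2 when
validation loss fails to improve for 7 consecutive epochs
(reduce-on-plateau; early stopping is available but off by default), and
the weights of the best validation epoch are restored after training.

## Evaluation metrics

Per-class one-vs-rest precision, recall, specificity and F1 are combined
with support weights n_c/N.  Under support weighting, weighted recall is
algebraically identical to overall accuracy — each class's recall is its
correct count over its support — and the test suite asserts this identity
on random configurations.  Accuracy is (TP + TN)/N; the ROC sweeps
thresholds over the distinct scores, plotting TPR = TP/(TP + FN) against
FPR = FP/(FP + TN) (i.e. 1 − specificity), and the AUC is the trapezoid
area, which equals the Mann–Whitney U statistic over n₊·n₋ (asserted
against scipy and scikit-learn).  Confidence intervals on proportions use
the 90 % normal approximation.

## Synthetic cohorts

The generator emulates the structure of a small two-class clinical TCD
cohort: 6 healthy and 12 ICU subjects by default, one 300 s recording
session each at 217 Hz.  A beat is a diastolic floor plus a systolic
Gaussian upstroke (peak 13 % into the cycle) and a smaller dicrotic
Gaussian (42 %); beats are concatenated with per-beat period jitter
(3 % sd) and additive Gaussian noise, clamped to (0, 300] cm/s.  Subject
parameters are drawn around class means; the ICU distribution has a
depressed diastolic floor (≈22 vs ≈45 cm/s), higher systolic peak, smaller
dicrotic wave and noisier envelopes, i.e. clearly elevated pulsatility.
Artifacts (NaN cuts, flat-line runs, spikes) are injected at Poisson rates
of 0.5 per recording each.

These class morphologies are a **design convention chosen so the synthetic
task is separable**, loosely inspired by the clinical observation that
raised intracranial pressure depresses diastolic flow; they are not fitted
to any clinical data.  Consequently the end-to-end experiment demonstrates
that the pipeline trains, remains session-independent and classifies a
separable two-class waveform population — it does not certify clinical
accuracy, and numbers obtained on synthetic cohorts say nothing about
performance on real TCD recordings.  Other simplifications: Gaussian beat
components rather than Windkessel dynamics, no respiratory or autoregulatory
modulation, no operator-dependent signal-quality drift, and a filled
rectangular Doppler spectrum rather than a physiologic velocity
distribution.

## Reference experiment sizes

The bundled reference experiment (`tcdonn.experiments`) trains
Self-ResAttentioNet18 at Q = 1 for 20 epochs on fold 0 of the default
18-subject cohort (~3.3 k overlapping training windows, ~120 validation and
~300 non-overlapping test windows) and evaluates on the held-out sessions.
Twenty epochs at these sizes converge comfortably on the separable
synthetic task; the full 100-epoch schedule is the default for real use.

## Known limitations

- The adaptive-threshold tracer and the quality heuristic are
  faithful-in-spirit stand-ins validated by parameter recovery and
  composition tests; clinical tracing pipelines use richer signal-quality
  models.
- Only unidirectional (positive) flow is traced; no IQ demodulation.
- Metrics generalize beyond two classes only via one-vs-rest weighting.
- The numpy engine targets CPU and small models; it has no GPU path.
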