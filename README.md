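# tcdonn

Self-organized operational neural networks (Self-ONNs) for classifying
transcranial-Doppler (TCD) blood-flow waveforms.

Continuous TCD ultrasound of the middle cerebral artery yields a 1D maximal
cerebral blood-flow-velocity (CBFV) envelope whose beat-to-beat morphology
changes with neurocritical conditions (hydrocephalus, traumatic brain
injury, hemorrhage).  `tcdonn` implements the full desk-side pipeline for
turning such recordings into a healthy-vs-ICU classifier, for researchers
working on physiological time-series classification:

- **Operational convolutions.**  Each generative neuron computes
  `x_k[m] = b_k + Σ_i Σ_r Σ_{q=1..Q} w_{k,i}[r,q] · y_i[m·s+r−p]^q` — a
  convolution over the first `Q` powers of its input, i.e. a learned
  truncated Taylor series per connection.  `Q = 1` recovers an ordinary
  CNN layer.
- **Architectures.**  `Self-ResNet18` (the 18-weighted-layer residual
  topology with operational layers and tanh activations, channel widths
  8→16→32→64) and `Self-ResAttentioNet18` (the same plus one 2-head
  attention layer per stage, querying the block input against the block
  output).  Both run on a small numpy automatic-differentiation engine
  bundled with the package (`tcdonn.nn`) — no deep-learning framework
  required.
- **Envelope extraction.**  STFT → velocity axis (1.75 MHz carrier) →
  Otsu binarization → 0.03 s × 5 cm/s median despeckle → per-column
  maximal-velocity tracing with range and continuity sanity checks,
  resampled to 217 Hz.
- **Preprocessing.**  Signal-cut removal, 1024-sample windows with 80 %
  overlap augmentation (training only), clear/corrupted/rejected quality
  annotation.
- **Session-independent 5-fold harness.**  Whole sessions are assigned to
  exactly one test fold; a run-time guard enforces disjointness.  Training
  uses Adam (lr 1e−4, batch 4), softmax-MSE loss, and a ×0.2
  reduce-on-plateau schedule with patience 7.
- **Weighted metrics.**  Support-weighted precision/recall/F1/specificity
  (weighted recall ≡ overall accuracy by construction), ROC and trapezoid
  AUC.
- **Synthetic cohorts.**  A pulsatile-waveform generator (6 healthy / 12
  ICU subjects by default, with NaN cuts, flat lines and speckled
  spectrograms) makes the whole pipeline testable without any clinical
  data.

## Worked example

```python
from tcdonn.synthetic import SyntheticCohortSpec, generate_cohort
from tcdonn.cv_harness import (TrainConfig, make_session_folds,
                               prepare_fold_arrays, train_fold, evaluate_fold)
from tcdonn.architectures import ArchitectureSpec, SelfResNet

spec = SyntheticCohortSpec(duration_s=60.0, seed=0)      # quick 60 s sessions
manifest, envelopes = generate_cohort(spec)
plan = make_session_folds(manifest, k=5, seed=0)
fold = plan.folds[0]
print("test sessions:", fold.test_sessions)

train_data, val_data, test_data = prepare_fold_arrays(
    manifest, envelopes, fold, train_overlap=0.8)
print("train/val/test segments:",
      len(train_data[0]), len(val_data[0]), len(test_data[0]))

net = SelfResNet(ArchitectureSpec(taylor_order=1, attention_enabled=True), seed=0)
history = train_fold(net, train_data, val_data, TrainConfig(n_epochs=3, seed=0))
report = evaluate_fold(net, test_data)
print(f"held-out accuracy: {report.overall_accuracy:.3f}")
print(f"AUC:               {report.auc:.3f}")
print(f"weighted F1:       {report.weighted_f1:.3f}")
```

Output:

```
test sessions: ['S002', 'S004', 'S009', 'S011', 'S015']
train/val/test segments: 604 23 57
held-out accuracy: 1.000
AUC:               1.000
weighted F1:       1.000
```

The five test sessions were never seen during training; the 57 test windows
do not overlap each other.  Accuracy, AUC and F1 of 1.000 mean every
held-out window of this (deliberately separable) synthetic cohort was
classified correctly — the synthetic classes differ strongly in pulsatility,
so perfect scores here validate the pipeline, not clinical performance (see
`docs/methods.md`).

A command-line interface mirrors the library:

```bash
tcdonn synth --out cohort/ --seed 0
tcdonn split --manifest cohort/manifest.csv --k 5 --seed 0 --out folds.json
tcdonn train --manifest cohort/manifest.csv --folds folds.json --fold 0 \
             --q 1 --attention --out checkpoint.h5
tcdonn evaluate --checkpoint checkpoint.h5 --manifest cohort/manifest.csv \
                --folds folds.json --fold 0
tcdonn extract-envelope --in doppler.csv --fs 10000 --out envelope.csv
```

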