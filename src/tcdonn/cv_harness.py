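"""Session-independent k-fold training harness.

Whole recording sessions — never individual segments — are assigned to
train/validation/test, so overlapping windows from one session can never
straddle the evaluation boundary.  Per class, sessions are partitioned into
k disjoint, size-balanced test groups; the remaining sessions train, with
roughly 10 % of training segments (grouped by session when possible) held
out for validation.  A leakage guard re-checks disjointness at run time.

Training follows the reference recipe: Adam at learning rate 1e-4, batch
size 4, mean-squared error between the softmax probabilities and the one-hot
target ("SoftM_MSE"), and a reduce-on-plateau schedule (factor 0.2, patience
7 epochs on validation loss).  Inputs are z-scored with train-set statistics
— the operational layers' Taylor expansions are accurate for inputs near
zero.  The weights of the best validation epoch are restored at the end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .architectures import SelfResNet
from .envelope import VelocityEnvelope
from .metrics import ClassificationReport, classification_report
from .nn import Adam, ReduceLROnPlateau, Tensor
from .preprocess import CLASS_LABELS, SEGMENT_LENGTH, segment_envelope

__all__ = ["FoldAssignment", "FoldPlan", "TrainConfig", "TrainingHistory",
           "make_session_folds", "softm_mse_loss", "check_no_leakage",
           "prepare_fold_arrays", "train_fold", "evaluate_fold",
           "run_fold_experiment"]

CLASS_TO_INDEX = {label: i for i, label in enumerate(CLASS_LABELS)}


@dataclass
class FoldAssignment:
    train_sessions: list[str]
    val_sessions: list[str]
    test_sessions: list[str]


@dataclass
class FoldPlan:
    folds: list[FoldAssignment]
    val_fraction: float = 0.10

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump({"val_fraction": self.val_fraction,
                       "folds": [asdict(fold) for fold in self.folds]}, f, indent=2)

    @classmethod
    def from_json(cls, path) -> "FoldPlan":
        with open(path) as f:
            d = json.load(f)
        return cls([FoldAssignment(**fold) for fold in d["folds"]],
                   val_fraction=d["val_fraction"])


@dataclass(frozen=True)
class TrainConfig:
    n_folds: int = 5
    batch_size: int = 4
    n_epochs: int = 100
    learning_rate: float = 1e-4
    epoch_patience: int = 7
    learning_factor: float = 0.2
    loss: str = "SoftM_MSE"
    optimizer: str = "Adam"
    seed: int = 0
    early_stopping: bool = False

    def __post_init__(self):
        if min(self.n_folds, self.batch_size, self.n_epochs,
               self.epoch_patience) < 1 or self.learning_rate <= 0:
            raise ValueError("config values must be positive")
        if not 0 < self.learning_factor < 1:
            raise ValueError("learning_factor must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as f:
            return cls(**(yaml.safe_load(f) or {}))


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    best_epoch: int = -1


def make_session_folds(manifest: pd.DataFrame, k: int = 5, seed: int = 0,
                       val_fraction: float = 0.10) -> FoldPlan:
    """Partition each class's sessions into k disjoint test groups.

    Deterministic given `seed`.  Validation sessions are carved out of each
    fold's training sessions per class (at least one per class when the class
    has more than one training session).
    """
    if k < 2:
        raise ValueError("need k >= 2: k = 1 leaves no held-out training data")
    rng = np.random.default_rng(seed)
    sessions = manifest.drop_duplicates("session_id")
    by_class = {c: sorted(g["session_id"]) for c, g in sessions.groupby("class_label")}
    for c, sess in by_class.items():
        if len(sess) < k:
            raise ValueError(f"class {c!r} has {len(sess)} sessions; "
                             f"need at least k = {k}")
    groups: dict[str, list[list[str]]] = {}
    for c, sess in by_class.items():
        order = rng.permutation(len(sess))
        shuffled = [sess[i] for i in order]
        groups[c] = [shuffled[i::k] for i in range(k)]
    folds = []
    for i in range(k):
        test, train, val = [], [], []
        for c in by_class:
            test.extend(groups[c][i])
            rest = [s for j in range(k) if j != i for s in groups[c][j]]
            # session-grouped validation: peel sessions until ~val_fraction
            n_val = max(1, int(round(val_fraction * len(rest)))) if len(rest) > 1 else 0
            val.extend(rest[:n_val])
            train.extend(rest[n_val:])
        folds.append(FoldAssignment(sorted(train), sorted(val), sorted(test)))
    plan = FoldPlan(folds, val_fraction=val_fraction)
    check_no_leakage(plan)
    return plan


def check_no_leakage(plan: FoldPlan, partition: bool = True) -> None:
    """Assert session-independence: train/val/test disjoint within each fold
    and, when `partition` is set, test sets pairwise disjoint across folds
    and jointly covering all sessions."""
    all_sessions = set()
    for fold in plan.folds:
        tr, va, te = map(set, (fold.train_sessions, fold.val_sessions,
                               fold.test_sessions))
        if tr & te or va & te or tr & va:
            raise AssertionError("session leakage within a fold")
        all_sessions |= tr | va | te
    if not partition:
        return
    seen: set[str] = set()
    for fold in plan.folds:
        te = set(fold.test_sessions)
        if seen & te:
            raise AssertionError("a session appears in two test folds")
        seen |= te
    if seen != all_sessions:
        raise AssertionError("test folds do not cover every session")


def softm_mse_loss(log_probs: np.ndarray, target_class) -> float:
    """Mean squared error between softmax probabilities and the one-hot target.

    `log_probs` must come from a log-softmax head (rows of exp summing to 1);
    anything else is a contract violation.  For two classes the loss lies in
    [0, 1] and is zero only for an exactly one-hot correct prediction.
    """
    log_probs = np.atleast_2d(np.asarray(log_probs, dtype=np.float64))
    probs = np.exp(log_probs)
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("log_probs rows must be normalized log-probabilities")
    targets = np.atleast_1d(np.asarray(target_class, dtype=int))
    onehot = np.zeros_like(probs)
    onehot[np.arange(len(targets)), targets] = 1.0
    return float(((probs - onehot) ** 2).mean())


def _softm_mse_loss_tensor(log_probs: Tensor, targets: np.ndarray) -> Tensor:
    probs = log_probs.exp()
    onehot = np.zeros(probs.shape)
    onehot[np.arange(len(targets)), targets] = 1.0
    return (probs - Tensor(onehot)).pow_int(2).mean()


def prepare_fold_arrays(manifest: pd.DataFrame,
                        envelopes: dict[str, VelocityEnvelope],
                        fold: FoldAssignment, train_overlap: float = 0.8,
                        include_corrupted: bool = True):
    """Segment a cohort into (X, y, sessions) arrays for one fold.

    Training sessions are segmented with `train_overlap` (augmentation);
    validation and test sessions are segmented without overlap so evaluation
    windows never share samples.  Rejected segments are dropped everywhere;
    corrupted ones are kept by default.
    """
    keep = {"clear", "corrupted"} if include_corrupted else {"clear"}
    manual = {}
    if "quality" in manifest.columns:
        for _, row in manifest.drop_duplicates("session_id").iterrows():
            q = row["quality"]
            if isinstance(q, str) and q in {"clear", "corrupted", "rejected"}:
                manual[row["session_id"]] = q

    def build(session_ids, overlap):
        X, y, sess = [], [], []
        for sid in session_ids:
            env = envelopes[sid]
            segs = segment_envelope(env, overlap_fraction=overlap,
                                    manual_quality=manual.get(sid))
            for s in segs:
                if s.quality in keep:
                    X.append(s.samples)
                    y.append(CLASS_TO_INDEX[s.class_label])
                    sess.append(sid)
        if not X:
            return (np.empty((0, SEGMENT_LENGTH)), np.empty(0, dtype=int),
                    np.array(sess))
        return np.stack(X), np.array(y, dtype=int), np.array(sess)

    return (build(fold.train_sessions, train_overlap),
            build(fold.val_sessions, 0.0),
            build(fold.test_sessions, 0.0))


def _epoch_eval(net: SelfResNet, X: np.ndarray, y: np.ndarray,
                mean: float, scale: float, batch_size: int = 16):
    log_probs = net.predict_log_proba((X - mean) / scale, batch_size=batch_size)
    loss = softm_mse_loss(log_probs, y)
    acc = float((log_probs.argmax(axis=1) == y).mean())
    return loss, acc, log_probs


def train_fold(net: SelfResNet, train_data, val_data,
               config: TrainConfig) -> TrainingHistory:
    """Train one network on one fold's arrays; restores best-val weights."""
    (X_tr, y_tr, _), (X_va, y_va, _) = train_data, val_data
    if len(X_tr) == 0 or len(X_va) == 0:
        raise ValueError("empty training or validation split")
    rng = np.random.default_rng(config.seed)
    mean = float(X_tr.mean())
    scale = float(X_tr.std()) or 1.0
    net.input_mean, net.input_scale = mean, scale
    opt = Adam(net.parameters(), lr=config.learning_rate)
    sched = ReduceLROnPlateau(opt, factor=config.learning_factor,
                              patience=config.epoch_patience)
    history = TrainingHistory()
    best_val = np.inf
    best_state = net.state_dict()
    for epoch in range(config.n_epochs):
        net.train()
        order = rng.permutation(len(X_tr))
        epoch_loss = 0.0
        correct = 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            xb = ((X_tr[idx] - mean) / scale)[:, None, :]
            yb = y_tr[idx]
            out = net(Tensor(xb))
            loss = _softm_mse_loss_tensor(out, yb)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
            correct += int((out.data.argmax(axis=1) == yb).sum())
        history.train_loss.append(epoch_loss / len(order))
        history.train_accuracy.append(correct / len(order))
        val_loss, val_acc, _ = _epoch_eval(net, X_va, y_va, mean, scale)
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        history.learning_rate.append(opt.lr)
        if val_loss < best_val:
            best_val = val_loss
            best_state = net.state_dict()
            history.best_epoch = epoch
        sched.step(val_loss)
    net.load_state_dict(best_state)
    return history


def evaluate_fold(net: SelfResNet, test_data,
                  positive_class: int = CLASS_TO_INDEX["ICU"]
                  ) -> ClassificationReport:
    """Per-segment argmax predictions + softmax scores -> full report."""
    X_te, y_te, _ = test_data
    if len(X_te) == 0:
        raise ValueError("empty test split")
    mean = getattr(net, "input_mean", 0.0)
    scale = getattr(net, "input_scale", 1.0)
    log_probs = net.predict_log_proba((X_te - mean) / scale)
    preds = log_probs.argmax(axis=1)
    scores = np.exp(log_probs[:, positive_class])
    return classification_report(y_te, preds, scores=scores,
                                 positive_class=positive_class)


def run_fold_experiment(manifest: pd.DataFrame,
                        envelopes: dict[str, VelocityEnvelope],
                        fold: FoldAssignment, net: SelfResNet,
                        config: TrainConfig, train_overlap: float = 0.8):
    """Guarded end-to-end run on one fold: segment, train, evaluate."""
    check_no_leakage(FoldPlan([fold]), partition=False)
    train_data, val_data, test_data = prepare_fold_arrays(
        manifest, envelopes, fold, train_overlap=train_overlap)
    history = train_fold(net, train_data, val_data, config)
    report = evaluate_fold(net, test_data)
    return history, report
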