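"""Training loop, step-decay learning-rate schedule, loss and metrics.

The learning-rate policy is the "8-5 gradient" step decay

    lr_n = initial_lr * d ** floor((n - 1) / p)

with decay factor d = 0.85 applied every p = 4 epochs from a base rate of
0.01 — piecewise constant, non-increasing, 25 distinct plateaus over a
100-epoch run.  Optimization is plain SGD with momentum on a softmax
cross-entropy objective; evaluation reports per-class and macro-averaged
accuracy, precision, recall and F1 from the one-vs-rest reading of the
confusion matrix:

    Acc = (TP + TN) / (TP + FP + FN + TN)      P  = TP / (TP + FP)
    R   = TP / (TP + FN)                       F1 = 2 TP / (2 TP + FP + FN)
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .nets import Network

EPS = 1e-12


# ---------------------------------------------------------------------------
# learning-rate schedule


@dataclass(frozen=True)
class LRSchedule:
    initial_lr: float = 0.01
    d: float = 0.85       # decay factor
    p: int = 4            # epochs per decay step

    def __post_init__(self):
        if not 0.0 < self.d <= 1.0:
            raise ValueError(f"decay factor must be in (0, 1], got {self.d}")
        if self.p < 1 or self.initial_lr <= 0:
            raise ValueError("period must be >= 1 and initial_lr > 0")


def lr_at_epoch(n: int, s: LRSchedule = LRSchedule()) -> float:
    """Step-decay learning rate for 1-based epoch n."""
    if n < 1:
        raise ValueError(f"epoch index must be >= 1, got {n}")
    return s.initial_lr * s.d ** ((n - 1) // s.p)


# ---------------------------------------------------------------------------
# loss


def cross_entropy(p: np.ndarray, true_class: int, M: int | None = None) -> float:
    """-log p_true for one normalized probability vector."""
    p = np.asarray(p, dtype=np.float64)
    if M is not None and p.shape[-1] != M:
        raise ValueError(f"expected {M} class probabilities, got {p.shape[-1]}")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"probabilities sum to {p.sum():.8f}, not 1")
    return float(-np.log(max(p[true_class], EPS)))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def batch_cross_entropy(logits: np.ndarray, targets: np.ndarray
                        ) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy of a batch and its gradient wrt logits."""
    n = logits.shape[0]
    probs = softmax(logits.astype(np.float64))
    loss = float(-np.log(np.maximum(
        probs[np.arange(n), targets], EPS)).mean())
    grad = probs
    grad[np.arange(n), targets] -= 1.0
    return loss, (grad / n).astype(np.float32)


# ---------------------------------------------------------------------------
# confusion matrix and metrics


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (M, M); rows = true class, columns = predicted

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def M(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, c: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for class c."""
        tp = int(self.counts[c, c])
        fp = int(self.counts[:, c].sum()) - tp
        fn = int(self.counts[c, :].sum()) - tp
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn


def confusion_matrix(pred, truth, M: int) -> ConfusionMatrix:
    pred = np.asarray(pred, dtype=np.int64)
    truth = np.asarray(truth, dtype=np.int64)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    if ((pred < 0) | (pred >= M) | (truth < 0) | (truth >= M)).any():
        raise ValueError(f"labels must lie in [0, {M})")
    counts = np.zeros((M, M), dtype=np.int64)
    np.add.at(counts, (truth, pred), 1)
    return ConfusionMatrix(counts)


@dataclass
class MetricsReport:
    """Per-class and macro-averaged metrics, as fractions in [0, 1]."""

    accuracy: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro: dict[str, float] = field(default_factory=dict)

    @property
    def micro_accuracy(self) -> float:
        return self.macro["micro_accuracy"]


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator in {what}; reporting 0", stacklevel=3)
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, precision, recall and F1 per class plus unweighted macro
    averages (and micro accuracy = trace / total)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    M = cm.M
    acc = np.zeros(M)
    prec = np.zeros(M)
    rec = np.zeros(M)
    f1 = np.zeros(M)
    for c in range(M):
        tp, fp, fn, tn = cm.one_vs_rest(c)
        acc[c] = (tp + tn) / (tp + fp + fn + tn)
        prec[c] = _safe_div(tp, tp + fp, f"precision of class {c}")
        rec[c] = _safe_div(tp, tp + fn, f"recall of class {c}")
        f1[c] = _safe_div(2 * tp, 2 * tp + fp + fn, f"F1 of class {c}")
    macro = {
        "accuracy": float(acc.mean()),
        "precision": float(prec.mean()),
        "recall": float(rec.mean()),
        "f1": float(f1.mean()),
        "micro_accuracy": float(np.trace(cm.counts) / cm.total),
    }
    return MetricsReport(acc, prec, rec, f1, macro)


# ---------------------------------------------------------------------------
# training


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 64
    momentum: float = 0.9
    weight_decay: float = 0.0
    seed: int = 0
    schedule: LRSchedule = field(default_factory=LRSchedule)

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


@dataclass
class EpochRecord:
    epoch: int
    lr: float
    train_loss: float
    val_loss: float
    val_accuracy: float


@dataclass
class TrainResult:
    history: list[EpochRecord]
    best_epoch: int
    best_val_accuracy: float
    best_state: dict[str, np.ndarray]


def predict(net: Network, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Class predictions in eval mode (running-statistic normalization)."""
    out = []
    for i in range(0, len(X), batch_size):
        logits = net.forward(X[i:i + batch_size], train=False)
        out.append(logits.argmax(axis=1))
    return np.concatenate(out)


def _eval_loss_acc(net, X, y, batch_size):
    losses, correct = [], 0
    for i in range(0, len(X), batch_size):
        logits = net.forward(X[i:i + batch_size], train=False)
        loss, _ = batch_cross_entropy(logits, y[i:i + batch_size])
        losses.append(loss * len(logits))
        correct += int((logits.argmax(axis=1) == y[i:i + batch_size]).sum())
    return sum(losses) / len(X), correct / len(X)


def train(net: Network, data: dict, cfg: TrainConfig = TrainConfig()
          ) -> TrainResult:
    """SGD training with the step-decay schedule.

    ``data`` maps "train" and "val" to (X, y) arrays with X of shape
    (N, 3, S, S) and integer labels y.  The best-validation-accuracy state
    (ties broken by the earlier epoch) is kept and returned.
    """
    Xtr, ytr = data["train"]
    Xva, yva = data["val"]
    if len(Xtr) == 0 or len(Xva) == 0:
        raise ValueError("empty train or validation split")
    M = net.config.num_classes
    for name, y in (("train", ytr), ("val", yva)):
        if y.min() < 0 or y.max() >= M:
            raise ValueError(
                f"{name} labels exceed the network's {M} classes")
    rng = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence([cfg.seed, 0xD1CE])))
    params = net.parameters()
    velocity = [np.zeros_like(v) for _, v, _ in params]
    history: list[EpochRecord] = []
    best = (-1.0, -1)  # (accuracy, -epoch) maximized
    best_state = net.state()
    for epoch in range(1, cfg.epochs + 1):
        lr = lr_at_epoch(epoch, cfg.schedule)
        order = rng.permutation(len(Xtr))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            net.zero_grad()
            logits = net.forward(Xtr[idx], train=True)
            loss, grad = batch_cross_entropy(logits, ytr[idx])
            net.backward(grad)
            for (name, v, g), vel in zip(params, velocity):
                if cfg.weight_decay:
                    g = g + cfg.weight_decay * v
                vel *= cfg.momentum
                vel -= lr * g
                v += vel
            losses.append(loss * len(idx))
        train_loss = sum(losses) / len(Xtr)
        val_loss, val_acc = _eval_loss_acc(net, Xva, yva, cfg.batch_size)
        history.append(EpochRecord(epoch, lr, train_loss, val_loss, val_acc))
        if val_acc > best[0]:
            best = (val_acc, epoch)
            best_state = net.state()
    return TrainResult(history, best_epoch=best[1],
                       best_val_accuracy=best[0], best_state=best_state)


def evaluate(net: Network, X: np.ndarray, y: np.ndarray,
             batch_size: int = 64) -> tuple[ConfusionMatrix, MetricsReport]:
    """Confusion matrix and metrics of a trained network on labeled data."""
    pred = predict(net, X, batch_size)
    cm = confusion_matrix(pred, y, net.config.num_classes)
    return cm, metrics(cm)
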