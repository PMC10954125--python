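"""Softmax classifier head, stratified splitting, and evaluation statistics.

The head is a dense network (input -> hidden ReLU -> softmax over the
eight diagnosis classes) trained by minibatch RMSprop on categorical
cross-entropy, mirroring the reference training configuration: learning
rate 0.001, batch size 32, 40 epochs, and a stratified 70:20:10
train:test:validation split.  Evaluation covers the 8x8 confusion
matrix, per-class and macro one-vs-rest accuracy / precision / recall /
F1, macro one-vs-rest ROC AUC, the cross-entropy loss trace, and a
one-way ANOVA utility for comparing model accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score

from .exceptions import DegenerateInputError, DomainError


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 40
    hidden: int = 512
    weight_decay: float = 0.0
    split: tuple[float, float, float] = (0.7, 0.2, 0.1)  # train : test : validation
    seed: int = 0

    def validate(self) -> None:
        if min(self.learning_rate, self.batch_size, self.epochs, self.hidden) <= 0:
            raise DomainError("hyperparameters must be positive")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise DomainError("split fractions must sum to 1")


@dataclass
class LossRecord:
    cross_entropy: list[float] = field(default_factory=list)  # per epoch
    mean_abs_error: float = 0.0  # |y - y_hat| diagnostic on one-hot targets


def split_dataset(
    labels: np.ndarray,
    fractions: tuple[float, float, float] = (0.7, 0.2, 0.1),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified, disjoint, exhaustive train/test/validation index sets.

    Within every class the indices are shuffled (seeded) and cut by a
    largest-remainder apportionment of the fractions, so per-class
    proportions are within one sample of the target.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise DomainError("fractions must sum to 1")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        if members.size < 3:
            raise DomainError(f"class {c!r} has fewer than 3 samples; cannot split three ways")
        rng.shuffle(members)
        n = members.size
        quota = np.array([f * n for f in fractions])
        alloc = np.floor(quota).astype(int)
        rem = quota - alloc
        for _ in range(n - alloc.sum()):
            k = int(np.argmax(rem))
            alloc[k] += 1
            rem[k] = -1
        stops = np.cumsum(alloc)
        parts[0].extend(members[: stops[0]])
        parts[1].extend(members[stops[0] : stops[1]])
        parts[2].extend(members[stops[1] :])
    return tuple(np.sort(np.asarray(p, dtype=np.int64)) for p in parts)  # type: ignore[return-value]


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean categorical cross-entropy, natural log, probabilities clipped at 1e-12."""
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    labels = np.asarray(labels, dtype=np.int64)
    if probs.shape[0] != labels.shape[0]:
        raise DomainError("probability rows and labels differ in length")
    if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6):
        raise DomainError("probability rows must sum to 1")
    p = np.clip(probs[np.arange(len(labels)), labels], 1e-12, 1.0)
    return float(-np.mean(np.log(p)))


class ClassifierHead:
    """Dense softmax head: input -> hidden (ReLU) -> n_classes (softmax)."""

    def __init__(self, n_features: int, n_classes: int = 8, hidden: int = 512, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.w1 = rng.normal(0, np.sqrt(2.0 / n_features), size=(hidden, n_features))
        self.b1 = np.zeros(hidden)
        self.w2 = rng.normal(0, np.sqrt(2.0 / hidden), size=(n_classes, hidden))
        self.b2 = np.zeros(n_classes)
        self.n_features = n_features
        self.n_classes = n_classes

    @property
    def n_parameters(self) -> int:
        return self.w1.size + self.b1.size + self.w2.size + self.b2.size

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_features:
            raise DomainError(f"expected {self.n_features} features, got {X.shape[1]}")
        h = np.maximum(X @ self.w1.T + self.b1, 0.0)
        z = h @ self.w2.T + self.b2
        z -= z.max(axis=1, keepdims=True)
        ez = np.exp(z)
        return ez / ez.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


def train_head(
    head: ClassifierHead,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig | None = None,
) -> LossRecord:
    """Minibatch RMSprop on categorical cross-entropy; trains in place.

    RMSprop keeps an exponential moving average (decay 0.9) of squared
    gradients and scales each step by its square root.  Shuffling is
    seeded, so two runs with the same seed produce identical weights.
    """
    if config is None:
        config = TrainConfig()
    config.validate()
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.int64)
    if X.shape[1] != head.n_features:
        raise DomainError(f"expected {head.n_features} features, got {X.shape[1]}")
    n = X.shape[0]
    rng = np.random.default_rng(config.seed)
    params = [head.w1, head.b1, head.w2, head.b2]
    cache = [np.zeros_like(p) for p in params]
    decay, eps = 0.9, 1e-8
    record = LossRecord()

    onehot = np.eye(head.n_classes)[y]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, tb = X[idx], onehot[idx]
            h_pre = xb @ head.w1.T + head.b1
            h = np.maximum(h_pre, 0.0)
            z = h @ head.w2.T + head.b2
            z -= z.max(axis=1, keepdims=True)
            ez = np.exp(z)
            p = ez / ez.sum(axis=1, keepdims=True)
            m = len(idx)
            dz = (p - tb) / m
            grads = [None] * 4
            grads[2] = dz.T @ h + config.weight_decay * head.w2
            grads[3] = dz.sum(axis=0)
            dh = (dz @ head.w2) * (h_pre > 0)
            grads[0] = dh.T @ xb + config.weight_decay * head.w1
            grads[1] = dh.sum(axis=0)
            for pth, g, c in zip(params, grads, cache):
                c *= decay
                c += (1 - decay) * g * g
                pth -= config.learning_rate * g / (np.sqrt(c) + eps)
        probs = head.predict_proba(X)
        record.cross_entropy.append(cross_entropy(probs, y))
    record.mean_abs_error = float(np.mean(np.abs(np.eye(head.n_classes)[y] - head.predict_proba(X))))
    return record


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int = 8) -> np.ndarray:
    """Counts matrix: entry (i, j) = samples of true class i predicted as j."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    for arr in (y_true, y_pred):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise DomainError("label outside the class range")
    if y_true.size == 0:
        return np.zeros((n_classes, n_classes), dtype=np.int64)
    return _sk_confusion(y_true, y_pred, labels=np.arange(n_classes))


@dataclass
class MetricsReport:
    confusion: np.ndarray
    per_class: dict  # name -> (n_classes,) arrays: acc, prec, rec, f1, tp, fp, fn, tn
    accuracy: float  # overall multiclass accuracy (trace / total)
    macro_acc: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    auc_macro: float | None = None
    loss_trace: list[float] = field(default_factory=list)
    degenerate_classes: list[int] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"overall accuracy : {self.accuracy:.4f}",
            f"macro precision  : {self.macro_precision:.4f}",
            f"macro recall     : {self.macro_recall:.4f}",
            f"macro F1         : {self.macro_f1:.4f}",
        ]
        if self.auc_macro is not None:
            lines.append(f"macro OvR AUC    : {self.auc_macro:.4f}")
        return "\n".join(lines)


def metrics_from_confusion(confusion: np.ndarray) -> MetricsReport:
    """Per-class one-vs-rest ACC/PREC/REC/F1 plus macro averages.

    ACC = (TP+TN)/(TP+FN+FP+TN), REC = TP/(TP+FN), PREC = TP/(TP+FP),
    F1 = 2*PREC*REC/(PREC+REC).  A zero denominator yields 0 and the
    class index is flagged degenerate.
    """
    c = np.asarray(confusion, dtype=np.float64)
    if c.ndim != 2 or c.shape[0] != c.shape[1] or np.any(c < 0):
        raise DomainError("confusion must be a square non-negative matrix")
    total = c.sum()
    tp = np.diag(c)
    fp = c.sum(axis=0) - tp
    fn = c.sum(axis=1) - tp
    tn = total - tp - fp - fn

    degenerate: list[int] = []

    def safe(num: np.ndarray, den: np.ndarray) -> np.ndarray:
        out = np.zeros_like(num, dtype=np.float64)
        ok = den > 0
        out[ok] = num[ok] / den[ok]
        for k in np.flatnonzero(~ok):
            if int(k) not in degenerate:
                degenerate.append(int(k))
        return out

    acc = safe(tp + tn, tp + fn + fp + tn)
    rec = safe(tp, tp + fn)
    prec = safe(tp, tp + fp)
    f1 = safe(2 * prec * rec, prec + rec)

    return MetricsReport(
        confusion=c.astype(np.int64),
        per_class={"acc": acc, "prec": prec, "rec": rec, "f1": f1, "tp": tp, "fp": fp, "fn": fn, "tn": tn},
        accuracy=float(tp.sum() / total) if total else 0.0,
        macro_acc=float(acc.mean()),
        macro_precision=float(prec.mean()),
        macro_recall=float(rec.mean()),
        macro_f1=float(f1.mean()),
        degenerate_classes=degenerate,
    )


def auc_ovr(y_true: np.ndarray, probs: np.ndarray) -> float:
    """Macro one-vs-rest ROC AUC by rank statistic (midrank tie handling).

    Classes absent from ``y_true`` are excluded (with a warning via the
    returned average over present classes only).
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    aucs = []
    for c in range(probs.shape[1]):
        pos = y_true == c
        if pos.all() or not pos.any():
            continue
        aucs.append(roc_auc_score(pos.astype(int), probs[:, c]))
    if not aucs:
        raise DegenerateInputError("no class with both positives and negatives")
    return float(np.mean(aucs))


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and upper-tail p value."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise DomainError("need at least two groups of at least two values")
    arrs = [np.asarray(g, dtype=np.float64) for g in groups]
    pooled_within = sum(float(np.var(a, ddof=1)) * (len(a) - 1) for a in arrs)
    if pooled_within == 0:
        raise DegenerateInputError("zero within-group variance")
    f, p = stats.f_oneway(*arrs)
    return float(f), float(p)
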