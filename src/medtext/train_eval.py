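"""Seeded training, evaluation metrics, and hyperparameter grid sweeps.

Metrics follow the usual confusion-matrix definitions — accuracy
(TP+TN)/(TP+FN+TN+FP), recall TP/(TP+FN), precision TP/(TP+FP) and
F1 = 2PR/(P+R) — reported as percentages.  For more than two classes the
per-class one-vs-rest precision/recall are averaged (macro by default,
micro available) and F1 is formed from the averaged pair, matching how a
single precision/recall/F1 triple is conventionally reported for a
multiclass task.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .autodiff import Tensor
from .neural_core import cross_entropy_loss
from .tokenize_embed import EncodedBatch

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig", "TrainingDiverged", "TrainHistory",
    "ConfusionCounts", "MetricsReport", "SweepResult",
    "train_model", "predict_labels", "confusion_counts",
    "metrics_from_counts", "f1_score", "evaluate_model", "grid_sweep",
    "sweep_table",
]


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

_EPS = 1e-8


class _Optimizer:
    def __init__(self, lr: float):
        self.lr = lr
        self.t = 0
        self.state: dict[int, dict[str, np.ndarray]] = {}

    def step(self, params: Sequence[Tensor]) -> None:
        self.t += 1
        for i, p in enumerate(params):
            g = p.grad
            if g is None:
                continue
            p.data -= self._delta(i, p, g)

    def _slot(self, i: int, like: np.ndarray, names: Sequence[str]):
        if i not in self.state:
            self.state[i] = {n: np.zeros_like(like) for n in names}
        return self.state[i]

    def _delta(self, i, p, g):  # pragma: no cover - abstract
        raise NotImplementedError


class _SGD(_Optimizer):
    def _delta(self, i, p, g):
        return self.lr * g


class _AdaGrad(_Optimizer):
    def _delta(self, i, p, g):
        s = self._slot(i, g, ["acc"])
        s["acc"] += g * g
        return self.lr * g / (np.sqrt(s["acc"]) + _EPS)


class _Adam(_Optimizer):
    beta1, beta2 = 0.9, 0.999

    def _delta(self, i, p, g):
        s = self._slot(i, g, ["m", "v"])
        s["m"] = self.beta1 * s["m"] + (1 - self.beta1) * g
        s["v"] = self.beta2 * s["v"] + (1 - self.beta2) * g * g
        m_hat = s["m"] / (1 - self.beta1**self.t)
        v_hat = s["v"] / (1 - self.beta2**self.t)
        return self.lr * m_hat / (np.sqrt(v_hat) + _EPS)


class _Nadam(_Adam):
    def _delta(self, i, p, g):
        s = self._slot(i, g, ["m", "v"])
        s["m"] = self.beta1 * s["m"] + (1 - self.beta1) * g
        s["v"] = self.beta2 * s["v"] + (1 - self.beta2) * g * g
        m_hat = s["m"] / (1 - self.beta1 ** (self.t + 1))
        v_hat = s["v"] / (1 - self.beta2**self.t)
        m_bar = self.beta1 * m_hat + (1 - self.beta1) * g / (1 - self.beta1**self.t)
        return self.lr * m_bar / (np.sqrt(v_hat) + _EPS)


_OPTIMIZERS = {"sgd": _SGD, "adagrad": _AdaGrad, "adam": _Adam, "nadam": _Nadam}


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; all randomness (shuffling, dropout) derives
    from ``seed``."""

    batch_size: int = 512
    optimizer: str = "adam"
    learning_rate: float = 0.01
    epochs: int = 10
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning rate must be >= 0")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size must be >= 1 and epochs >= 0")
        if self.optimizer not in _OPTIMIZERS:
            raise ValueError(f"unknown optimizer {self.optimizer!r}; "
                             f"choose from {sorted(_OPTIMIZERS)}")


class TrainingDiverged(RuntimeError):
    pass


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    @property
    def epochs_run(self) -> int:
        return len(self.train_loss)

    def best_val_accuracy(self) -> float:
        return max(self.val_accuracy) if self.val_accuracy else float("nan")


def train_model(model, train: EncodedBatch, val: EncodedBatch,
                config: TrainConfig) -> TrainHistory:
    """Minimize the cross-entropy of the model on ``train`` with the
    configured optimizer, tracking per-epoch mean loss and validation
    accuracy.  Stops early when validation accuracy has not improved for
    ``patience`` consecutive epochs.  A non-finite loss aborts with
    :class:`TrainingDiverged` naming the epoch and batch."""
    rng = np.random.default_rng(config.seed)
    opt = _OPTIMIZERS[config.optimizer](config.learning_rate)
    params = list(model.params().values())
    history = TrainHistory()
    best_acc, since_best = -1.0, 0
    n = len(train)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            batch = train.take(order[lo : lo + config.batch_size])
            for p in params:
                p.zero_grad()
            probs = model.forward_batch(batch, train=True, rng=rng)
            loss = cross_entropy_loss(probs, batch.labels)
            lval = float(loss.data)
            if not np.isfinite(lval):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch + 1}, batch {lo // config.batch_size + 1}")
            loss.backward()
            opt.step(params)
            losses.append(lval)
        history.train_loss.append(float(np.mean(losses)))
        val_acc = float(np.mean(predict_labels(model, val) == val.labels))
        history.val_accuracy.append(val_acc)
        if val_acc > best_acc + 1e-12:
            best_acc, since_best = val_acc, 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    return history


def predict_labels(model, batch: EncodedBatch, chunk: int = 256) -> np.ndarray:
    """Argmax class per document (ties resolve to the lowest class index,
    numpy's first-maximum rule)."""
    out = []
    for lo in range(0, len(batch), chunk):
        probs = model.predict_proba(batch.take(np.arange(lo, min(lo + chunk, len(batch)))))
        out.append(np.argmax(probs, axis=-1))
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


@dataclass
class ConfusionCounts:
    """One-vs-rest TP/TN/FP/FN per class; for each class the four counts
    sum to N."""

    per_class: dict[int, dict[str, int]]
    n_classes: int
    N: int


def confusion_counts(pred: np.ndarray, truth: np.ndarray, n_classes: int) -> ConfusionCounts:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred/truth length mismatch")
    if max(pred.max(initial=0), truth.max(initial=0)) >= n_classes:
        raise ValueError("labels out of range")
    per = {}
    for c in range(n_classes):
        tp = int(np.sum((pred == c) & (truth == c)))
        fp = int(np.sum((pred == c) & (truth != c)))
        fn = int(np.sum((pred != c) & (truth == c)))
        tn = int(np.sum((pred != c) & (truth != c)))
        per[c] = {"TP": tp, "TN": tn, "FP": fp, "FN": fn}
    return ConfusionCounts(per_class=per, n_classes=n_classes, N=int(pred.size))


@dataclass
class MetricsReport:
    """Accuracy/precision/recall/F1 as percentages in [0, 100]."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    averaging: str = "binary"

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1}


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("zero denominator computing %s; reporting 0", what)
        return 0.0
    return num / den


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R) on the percentage scale, rounded to two
    decimals; 0 when both inputs are 0."""
    if precision + recall == 0:
        return 0.0
    return round(2 * precision * recall / (precision + recall), 2)


def metrics_from_counts(counts: ConfusionCounts, average: str = "auto") -> MetricsReport:
    """Percent metrics from confusion counts.

    ``average="auto"``: with two classes, class 1 is the positive class
    and the confusion-matrix formulas apply verbatim; with more, the
    macro (unweighted per-class mean) one-vs-rest precision/recall are
    reported.  ``"macro"`` / ``"micro"`` force that averaging for any
    class count.  Accuracy is always the exact-match fraction, and F1 is
    the harmonic mean of the reported precision/recall pair.
    """
    if counts.N == 0:
        raise ValueError("empty prediction set")
    if average == "auto":
        average = "binary" if counts.n_classes == 2 else "macro"
    if average == "binary":
        if counts.n_classes != 2:
            raise ValueError("binary averaging needs exactly 2 classes")
        c = counts.per_class[1]
        acc = _safe_div(c["TP"] + c["TN"], counts.N, "accuracy")
        prec = _safe_div(c["TP"], c["TP"] + c["FP"], "precision")
        rec = _safe_div(c["TP"], c["TP"] + c["FN"], "recall")
        avg = "binary"
    else:
        acc = _safe_div(sum(c["TP"] for c in counts.per_class.values()), counts.N,
                        "accuracy")
        if average == "macro":
            prec = float(np.mean([_safe_div(c["TP"], c["TP"] + c["FP"], "precision")
                                  for c in counts.per_class.values()]))
            rec = float(np.mean([_safe_div(c["TP"], c["TP"] + c["FN"], "recall")
                                 for c in counts.per_class.values()]))
        elif average == "micro":
            tp = sum(c["TP"] for c in counts.per_class.values())
            fp = sum(c["FP"] for c in counts.per_class.values())
            fn = sum(c["FN"] for c in counts.per_class.values())
            prec = _safe_div(tp, tp + fp, "precision")
            rec = _safe_div(tp, tp + fn, "recall")
        else:
            raise ValueError(f"unknown averaging mode {average!r}")
        avg = average
    acc_pct = round(100 * acc, 2)
    prec_pct = round(100 * prec, 2)
    rec_pct = round(100 * rec, 2)
    return MetricsReport(accuracy=acc_pct, precision=prec_pct, recall=rec_pct,
                         f1=f1_score(prec_pct, rec_pct), averaging=avg)


def evaluate_model(model, test: EncodedBatch, average: str = "auto") -> MetricsReport:
    """predict -> confusion counts -> percent metrics."""
    if len(test) == 0:
        raise ValueError("empty test set")
    pred = predict_labels(model, test)
    n_classes = model.spec.n_classes
    return metrics_from_counts(confusion_counts(pred, test.labels, n_classes),
                               average=average)


# ---------------------------------------------------------------------------
# grid sweeps
# ---------------------------------------------------------------------------

SWEEP_AXES = ("kernel_widths", "learning_rate", "dropout", "optimizer",
              "activation", "bigru_layers")


@dataclass
class SweepResult:
    axis: str
    value: object
    dataset: str
    metrics: MetricsReport | None
    best: bool = False
    error: str | None = None


def grid_sweep(build_fn: Callable[[object, int], object], axis: str,
               values: Sequence, data: dict[str, EncodedBatch],
               base_config: TrainConfig,
               dataset: str = "synthetic") -> list[SweepResult]:
    """Train and evaluate one model per axis value, all other settings
    fixed; every cell uses the same seed.  ``build_fn(value, seed)`` must
    return a fresh model already configured for the axis value (for the
    model-structure axes) — the learning_rate and optimizer axes override
    the train config instead.  A failing cell is recorded and the sweep
    continues; the best row by test accuracy is marked."""
    if axis not in SWEEP_AXES:
        raise ValueError(f"unknown sweep axis {axis!r}; choose from {SWEEP_AXES}")
    if not values:
        raise ValueError("empty value list")
    results: list[SweepResult] = []
    for value in values:
        cfg = base_config
        if axis == "learning_rate":
            cfg = replace(base_config, learning_rate=float(value))
        elif axis == "optimizer":
            cfg = replace(base_config, optimizer=str(value))
        try:
            model = build_fn(value, cfg.seed)
            train_model(model, data["train"], data["val"], cfg)
            metrics = evaluate_model(model, data["test"])
            results.append(SweepResult(axis, value, dataset, metrics))
        except Exception as err:  # noqa: BLE001 - sweep must survive bad cells
            logger.warning("sweep cell %s=%r failed: %s", axis, value, err)
            results.append(SweepResult(axis, value, dataset, None, error=str(err)))
    scored = [r for r in results if r.metrics is not None]
    if scored:
        best = max(scored, key=lambda r: r.metrics.accuracy)
        best.best = True
    return results


def sweep_table(results: Sequence[SweepResult]):
    """Sweep results as a DataFrame with columns
    (axis, value, dataset, accuracy, precision, recall, f1, best)."""
    import pandas as pd

    rows = []
    for r in results:
        m = r.metrics.as_dict() if r.metrics else dict.fromkeys(
            ("accuracy", "precision", "recall", "f1"), float("nan"))
        rows.append({"axis": r.axis, "value": str(r.value), "dataset": r.dataset,
                     **m, "best": r.best, "error": r.error or ""})
    return pd.DataFrame(rows)
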