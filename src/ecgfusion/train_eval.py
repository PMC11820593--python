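"""Training loop and the evaluation-metric suite.

Training minimizes softmax cross-entropy with Adam (defaults: learning
rate 0.0007, batch size 256, 200 epochs, no weight decay and no
learning-rate schedule). When a validation set is supplied, the
parameters achieving the best validation overall accuracy are restored
at the end.

Evaluation reduces the 5 x 5 confusion matrix (rows = actual, columns =
predicted) one-vs-rest per class:

    Acc  = (TP + TN) / (TP + TN + FP + FN)
    PPV  = TP / (TP + FP)          Sen  = TP / (TP + FN)
    Spec = TN / (TN + FP)          F1   = 2 PPV Sen / (PPV + Sen)
    OA   = trace / total

A class never predicted has an undefined PPV; it is reported as 0 and
flagged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix

from .model import FusionNet
from .nnet import Adam, cross_entropy

__all__ = [
    "TrainConfig",
    "TrainResult",
    "EvalReport",
    "train",
    "evaluate",
    "metrics_from_confusion",
]

logger = logging.getLogger(__name__)

AAMI_CLASSES = ("N", "S", "V", "F", "Q")


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 7e-4
    batch_size: int = 256
    epochs: int = 200
    optimizer: str = "adam"
    loss: str = "cross_entropy"
    seed: int = 0
    #: stop after this many epochs without validation improvement
    #: (None = train the full epoch budget)
    early_stopping_patience: int | None = None

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.optimizer != "adam" or self.loss != "cross_entropy":
            raise ValueError("only adam + cross_entropy are supported")


@dataclass
class TrainResult:
    model: FusionNet
    history: dict[str, list[float]] = field(default_factory=dict)


def _encode_labels(y: np.ndarray, classes: tuple[str, ...]) -> np.ndarray:
    lut = {c: i for i, c in enumerate(classes)}
    return np.array([lut[v] for v in y], dtype=np.int64)


def train(
    model: FusionNet,
    train_data: tuple[np.ndarray, np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    cfg: TrainConfig | None = None,
    classes: tuple[str, ...] = AAMI_CLASSES,
) -> TrainResult:
    """Train ``model`` on ``(segments, images, labels)`` arrays.

    Labels may be class symbols or integer ids. Deterministic given
    ``cfg.seed`` (batch shuffling and dropout are the only stochastic
    elements). Returns per-epoch loss/accuracy curves.
    """
    cfg = cfg or TrainConfig()
    X1, X2, y = train_data
    y_idx = y if np.issubdtype(np.asarray(y).dtype, np.integer) else _encode_labels(y, classes)
    present = set(np.unique(y_idx).tolist())
    missing = [classes[i] for i in range(len(classes)) if i not in present]
    if missing:
        warnings.warn(f"classes absent from training set: {missing}", stacklevel=2)

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    history: dict[str, list[float]] = {"loss": [], "train_acc": [], "val_acc": []}
    best_val, best_state, stale = -np.inf, None, 0

    n = len(y_idx)
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = model.forward(X1[idx], X2[idx])
            loss = cross_entropy(logits, y_idx[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == y_idx[idx]).sum())
        history["loss"].append(float(np.mean(losses)))
        history["train_acc"].append(correct / n)

        if val_data is not None:
            va = _accuracy(model, val_data, classes)
            history["val_acc"].append(va)
            if va > best_val:
                best_val, best_state, stale = va, [a.copy() for a in model.state_arrays()], 0
            else:
                stale += 1
                if (
                    cfg.early_stopping_patience is not None
                    and stale >= cfg.early_stopping_patience
                ):
                    logger.info("early stop at epoch %d", epoch + 1)
                    break
        logger.info(
            "epoch %d/%d loss=%.4f acc=%.4f%s",
            epoch + 1, cfg.epochs, history["loss"][-1], history["train_acc"][-1],
            f" val={history['val_acc'][-1]:.4f}" if val_data is not None else "",
        )

    if best_state is not None:
        model.load_state_arrays(best_state)
    return TrainResult(model=model, history=history)


def _accuracy(
    model: FusionNet,
    data: tuple[np.ndarray, np.ndarray, np.ndarray],
    classes: tuple[str, ...],
    batch: int = 256,
) -> float:
    X1, X2, y = data
    y_idx = y if np.issubdtype(np.asarray(y).dtype, np.integer) else _encode_labels(y, classes)
    hits = 0
    for start in range(0, len(y_idx), batch):
        probs = model.predict_proba(X1[start : start + batch], X2[start : start + batch])
        hits += int((probs.argmax(axis=1) == y_idx[start : start + batch]).sum())
    return hits / len(y_idx)


@dataclass
class EvalReport:
    """Confusion matrix plus per-class and overall metrics."""

    confusion: np.ndarray
    classes: tuple[str, ...]
    per_class: dict[str, dict[str, float]]
    oa: float
    undefined_ppv: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class,
            "oa": self.oa,
            "undefined_ppv": list(self.undefined_ppv),
        }


def metrics_from_confusion(
    confusion: np.ndarray, classes: tuple[str, ...] = AAMI_CLASSES
) -> EvalReport:
    """Per-class one-vs-rest metrics and overall accuracy from a
    (rows = actual, cols = predicted) count matrix."""
    cm = np.asarray(confusion, dtype=np.int64)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.shape[0] != len(classes):
        raise ValueError("confusion matrix shape does not match classes")
    if (cm < 0).any():
        raise ValueError("confusion matrix entries must be nonnegative")
    total = int(cm.sum())
    per_class: dict[str, dict[str, float]] = {}
    undefined = []
    for i, name in enumerate(classes):
        tp = int(cm[i, i])
        fn = int(cm[i].sum() - tp)
        fp = int(cm[:, i].sum() - tp)
        tn = total - tp - fn - fp
        ppv = tp / (tp + fp) if tp + fp else 0.0
        if tp + fp == 0:
            undefined.append(name)
        sen = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        acc = (tp + tn) / total if total else 0.0
        f1 = 2 * ppv * sen / (ppv + sen) if ppv + sen else 0.0
        per_class[name] = {
            "PPV": ppv, "Sen": sen, "Spec": spec, "Acc": acc, "F1": f1,
            "support": tp + fn,
        }
    oa = float(np.trace(cm) / total) if total else 0.0
    return EvalReport(
        confusion=cm, classes=classes, per_class=per_class, oa=oa,
        undefined_ppv=tuple(undefined),
    )


def evaluate(
    model: FusionNet,
    test_data: tuple[np.ndarray, np.ndarray, np.ndarray],
    classes: tuple[str, ...] = AAMI_CLASSES,
    batch: int = 256,
) -> EvalReport:
    """Predict the test set and compute the full metric suite."""
    X1, X2, y = test_data
    if len(y) == 0:
        raise ValueError("test set is empty")
    y_idx = y if np.issubdtype(np.asarray(y).dtype, np.integer) else _encode_labels(y, classes)
    preds = []
    for start in range(0, len(y_idx), batch):
        probs = model.predict_proba(X1[start : start + batch], X2[start : start + batch])
        preds.append(probs.argmax(axis=1))
    pred = np.concatenate(preds)
    cm = confusion_matrix(y_idx, pred, labels=np.arange(len(classes)))
    return metrics_from_confusion(cm, classes)
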