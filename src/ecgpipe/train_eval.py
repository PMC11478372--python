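"""Training loop, hyperparameter sweep harness and classification scoring.

Training minimizes categorical cross-entropy (plus the dense layers' L2
penalty) with Adam, monitors validation loss for early stopping with
best-weight restoration, and records per-epoch curves. The sweep harness
retrains one model per configuration on identical data and reports the
validation-curve averages the way the published learning-rate/batch-size
tables are laid out. Evaluation produces a 5x5 confusion matrix with
per-class precision, recall and F1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from . import nn
from .io import CLASS_LABELS
from .model import ArchitectureConfig, build_model
from .preprocess import SegmentDataset

LABEL_TO_INDEX = {label: i for i, label in enumerate(CLASS_LABELS)}

#: The published sweep grids: learning rates at fixed batch 150, then
#: batch sizes at fixed learning rate 0.001.
LEARNING_RATE_GRID = (0.0006, 0.0007, 0.0008, 0.0009, 0.001, 0.0015, 0.002)
BATCH_SIZE_GRID = (70, 90, 110, 130, 150, 170, 190)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; defaults are the recommended operating point."""

    learning_rate: float = 0.001
    batch_size: int = 150
    max_epochs: int = 200
    early_stop_patience: int = 20
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class TrainHistory:
    """Per-epoch curves; ``stopped_epoch`` is the last completed epoch
    (1-based), which is below ``max_epochs`` when early stopping fired."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    stopped_epoch: int = 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(1, len(self.train_loss) + 1),
            "train_loss": self.train_loss,
            "train_accuracy": self.train_accuracy,
            "val_loss": self.val_loss,
            "val_accuracy": self.val_accuracy,
        })


@dataclass
class EvalReport:
    """5x5 confusion matrix (rows = truth, columns = prediction) with
    per-class precision/recall/F1 and overall accuracy. Classes whose
    metric denominator is zero score 0 and are listed in
    ``zero_division_classes``."""

    confusion: np.ndarray
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    accuracy: float
    labels: tuple[str, ...] = CLASS_LABELS
    zero_division_classes: tuple[str, ...] = ()

    def per_class_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }).loc[list(self.labels)]


def dataset_to_arrays(dataset: SegmentDataset | list) -> tuple[np.ndarray, np.ndarray]:
    """Stack segments into ``(X, y)``: X is (n, length, 1), y integer classes."""
    segments = dataset.segments if isinstance(dataset, SegmentDataset) else dataset
    if not segments:
        raise ValueError("dataset is empty")
    X = np.stack([seg.samples for seg in segments])[:, :, None]
    try:
        y = np.array([LABEL_TO_INDEX[seg.label] for seg in segments])
    except KeyError as exc:
        raise ValueError(f"label outside the five classes: {exc}") from exc
    return X, y


def _one_hot(y: np.ndarray, n_classes: int = len(CLASS_LABELS)) -> np.ndarray:
    out = np.zeros((y.size, n_classes))
    out[np.arange(y.size), y] = 1.0
    return out


def _evaluate_loss_acc(model: nn.Sequential, X: np.ndarray, y: np.ndarray,
                       batch_size: int = 512) -> tuple[float, float]:
    onehot = _one_hot(y)
    losses = []
    correct = 0
    for i in range(0, len(X), batch_size):
        logits = model.forward(X[i : i + batch_size], training=False)
        loss, _ = nn.softmax_cross_entropy(logits, onehot[i : i + batch_size])
        losses.append(loss * len(logits))
        correct += int(np.sum(logits.argmax(axis=1) == y[i : i + batch_size]))
    return sum(losses) / len(X) + model.l2_loss(), correct / len(X)


def train_model(
    model: nn.Sequential,
    train: tuple[np.ndarray, np.ndarray] | SegmentDataset,
    val: tuple[np.ndarray, np.ndarray] | SegmentDataset,
    config: TrainConfig | None = None,
) -> tuple[nn.Sequential, TrainHistory]:
    """Fit the classifier with Adam, early stopping and best-weight restore.

    ``train`` and ``val`` are either ``(X, y)`` arrays (y as integer class
    indices) or :class:`~ecgpipe.preprocess.SegmentDataset` objects. All
    shuffling and dropout noise derives from ``config.seed``, so identical
    inputs reproduce identical histories.
    """
    config = config or TrainConfig()
    X_train, y_train = train if isinstance(train, tuple) else dataset_to_arrays(train)
    X_val, y_val = val if isinstance(val, tuple) else dataset_to_arrays(val)
    if len(X_train) == 0 or len(X_val) == 0:
        raise ValueError("training and validation sets must be non-empty")
    if y_train.max() >= len(CLASS_LABELS) or y_train.min() < 0:
        raise ValueError("labels must index the five classes")
    onehot = _one_hot(y_train)
    optimizer = nn.Adam(model, learning_rate=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history = TrainHistory()
    best_val = np.inf
    best_weights = model.get_weights()
    since_best = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(X_train))
        epoch_loss = 0.0
        epoch_correct = 0
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            logits = model.forward(X_train[batch], training=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, onehot[batch])
            model.backward(dlogits)
            optimizer.step()
            epoch_loss += loss * len(batch)
            epoch_correct += int(np.sum(logits.argmax(axis=1) == y_train[batch]))
        history.train_loss.append(epoch_loss / len(order) + model.l2_loss())
        history.train_accuracy.append(epoch_correct / len(order))
        val_loss, val_acc = _evaluate_loss_acc(model, X_val, y_val)
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        history.stopped_epoch = epoch
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = model.get_weights()
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.early_stop_patience:
                break
    model.set_weights(best_weights)
    return model, history


def hyperparameter_sweep(
    grid: list[TrainConfig],
    train: tuple[np.ndarray, np.ndarray] | SegmentDataset,
    val: tuple[np.ndarray, np.ndarray] | SegmentDataset,
    architecture: ArchitectureConfig | None = None,
    model_seed: int = 0,
    tail_epochs: int = 20,
) -> tuple[pd.DataFrame, list[TrainHistory]]:
    """Train one freshly built model per configuration on identical data.

    Returns a table with one row per configuration — batch size, learning
    rate, the validation-curve averages (``avg_accuracy`` / ``avg_loss``
    over the full curve, which is the column mirroring the published
    sweep tables, plus the final-``tail_epochs`` means) — and the per-run
    histories. A failing cell records NaNs and the sweep continues.
    """
    if not grid:
        raise ValueError("sweep grid must be non-empty")
    rows = []
    histories: list[TrainHistory] = []
    for cfg in grid:
        try:
            model = build_model(architecture, seed=model_seed)
            _, history = train_model(model, train, val, cfg)
            va = np.asarray(history.val_accuracy)
            vl = np.asarray(history.val_loss)
            rows.append({
                "batch_size": cfg.batch_size,
                "learning_rate": cfg.learning_rate,
                "avg_accuracy": float(va.mean()),
                "avg_loss": float(vl.mean()),
                "tail_accuracy": float(va[-tail_epochs:].mean()),
                "tail_loss": float(vl[-tail_epochs:].mean()),
                "epochs": history.stopped_epoch,
                "error": "",
            })
            histories.append(history)
        except (ValueError, FloatingPointError) as exc:
            rows.append({
                "batch_size": cfg.batch_size, "learning_rate": cfg.learning_rate,
                "avg_accuracy": np.nan, "avg_loss": np.nan,
                "tail_accuracy": np.nan, "tail_loss": np.nan,
                "epochs": 0, "error": str(exc),
            })
            histories.append(TrainHistory())
    return pd.DataFrame(rows), histories


def learning_rate_grid(batch_size: int = 150,
                       rates: tuple[float, ...] = LEARNING_RATE_GRID,
                       **kwargs) -> list[TrainConfig]:
    return [TrainConfig(learning_rate=lr, batch_size=batch_size, **kwargs)
            for lr in rates]


def batch_size_grid(learning_rate: float = 0.001,
                    sizes: tuple[int, ...] = BATCH_SIZE_GRID,
                    **kwargs) -> list[TrainConfig]:
    return [TrainConfig(learning_rate=learning_rate, batch_size=bs, **kwargs)
            for bs in sizes]


def classification_report(y_true, y_pred, labels: tuple[str, ...] = CLASS_LABELS) -> EvalReport:
    """Confusion matrix and per-class precision/recall/F1.

    Accepts class labels either as strings from ``labels`` or as integer
    indices into it. Zero-denominator metrics score 0 and the affected
    classes are flagged.
    """
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape or yt.size == 0:
        raise ValueError("y_true and y_pred must share a non-zero length")
    if yt.dtype.kind in "iu":
        yt = np.asarray(labels)[yt]
    if yp.dtype.kind in "iu":
        yp = np.asarray(labels)[yp]
    conf = confusion_matrix(yt, yp, labels=list(labels))
    prec, rec, f1, support = precision_recall_fscore_support(
        yt, yp, labels=list(labels), zero_division=0)
    flagged = tuple(
        lab for lab, p, r, s in zip(labels, prec, rec, support)
        if (p == 0 and conf[:, list(labels).index(lab)].sum() == 0) or s == 0
    )
    return EvalReport(
        confusion=conf,
        precision={lab: float(v) for lab, v in zip(labels, prec)},
        recall={lab: float(v) for lab, v in zip(labels, rec)},
        f1={lab: float(v) for lab, v in zip(labels, f1)},
        accuracy=float(np.trace(conf) / conf.sum()),
        labels=tuple(labels),
        zero_division_classes=flagged,
    )


def evaluate_model(
    model: nn.Sequential,
    test: tuple[np.ndarray, np.ndarray] | SegmentDataset,
) -> EvalReport:
    """Predict on a held-out set and score it."""
    X, y = test if isinstance(test, tuple) else dataset_to_arrays(test)
    pred = model.predict_proba(X).argmax(axis=1)
    return classification_report(y, pred)
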