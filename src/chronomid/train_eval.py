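"""Training, evaluation and cross-run aggregation.

Evaluation is at the image level: each comparison slice (with its
difference map, for cross-modal variants) is one sample. The anabolic
(PTH) class is the positive class throughout; accuracy is

    (TP + TN) / (TP + TN + FP + FN)

which is appropriate because the generated splits are close to balanced.
Accuracies from repeated runs are macro-averaged (unweighted mean) with the
sample standard deviation reported as the error.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .models import ArchitectureSpec, Network, build_model
from .nn import Adam
from .partition import TEST, TRAIN, VAL, PartitionPlan
from .synthdata import PTH

CLASSES = (PTH, "wild")  # index 0 = positive class; argmax ties resolve here


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 5
    batch_size: int = 32
    seed: int = 0
    learning_rate: float = 3e-3
    l2_lambda: float = 0.0003
    run_count: int = 1

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class ConfusionMatrix:
    """TP/FP/TN/FN counts with PTH ('Anabolic') as the positive class."""

    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def __post_init__(self):
        for v in (self.TP, self.FP, self.TN, self.FN):
            if v < 0:
                raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class RunReport:
    accuracy: float
    confusion: ConfusionMatrix
    split_sizes: dict
    seed: int
    history: list = field(default_factory=list)
    wall_time_s: float = 0.0


@dataclass
class Arrays:
    """Model-ready tensors for one split."""

    images: np.ndarray
    diffs: np.ndarray | None
    weeks: np.ndarray
    y: np.ndarray

    def __len__(self):
        return len(self.images)

    def subset(self, idx):
        return Arrays(
            images=self.images[idx],
            diffs=None if self.diffs is None else self.diffs[idx],
            weeks=self.weeks[idx],
            y=self.y[idx],
        )


def encode_label(label: str) -> int:
    if label not in CLASSES:
        raise ValueError(f"unknown class label {label!r}")
    return CLASSES.index(label)


def arrays_from_samples(samples, with_diffs: bool) -> Arrays:
    images = np.stack([s.image for s in samples])
    diffs = np.stack([s.diff.values for s in samples]) if with_diffs else None
    weeks = np.array([s.week for s in samples], dtype=np.int64)
    y = np.array([encode_label(s.label) for s in samples], dtype=np.int64)
    return Arrays(images=images, diffs=diffs, weeks=weeks, y=y)


def split_samples(samples, plan: PartitionPlan):
    """Group preprocessed samples by the partition of their comparison image."""
    out = {TRAIN: [], VAL: [], TEST: []}
    for s in samples:
        out[plan.split_of_sample(s)].append(s)
    return out


def _onehot(y, n_classes):
    out = np.zeros((len(y), n_classes))
    out[np.arange(len(y)), y] = 1.0
    return out


def train(model: Network, data: dict, config: TrainConfig):
    """Train for a fixed number of epochs (no early stopping).

    ``data`` maps split names to :class:`Arrays`; 'train' is required and
    'val' is tracked per epoch when present. Returns the per-epoch history.
    """
    tr = data.get(TRAIN)
    if tr is None or len(tr) == 0:
        raise ValueError("empty training split")
    n_classes = model.spec.n_classes
    opt = Adam(model.params(), lr=config.learning_rate, l2=config.l2_lambda)
    rng = np.random.default_rng(config.seed)
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(tr))
        losses, correct = [], 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            batch = tr.subset(idx)
            logits = model.forward(batch.images, batch.diffs, batch.weeks, training=True)
            loss = model.loss.forward(logits, _onehot(batch.y, n_classes))
            opt.zero_grad()
            model.backward(model.loss.backward())
            opt.step()
            losses.append(loss + opt.penalty())
            correct += int((logits.argmax(axis=1) == batch.y).sum())
        row = {
            "epoch": epoch + 1,
            "train_loss": float(np.mean(losses)),
            "train_acc": correct / len(tr),
        }
        va = data.get(VAL)
        if va is not None and len(va):
            row["val_acc"] = evaluate_accuracy(model, va)
        history.append(row)
    return history


def predict(model: Network, arrays: Arrays) -> np.ndarray:
    probs = model.predict_proba(arrays.images, arrays.diffs, arrays.weeks)
    return probs.argmax(axis=1)  # argmax takes the first index on ties


def confusion(model: Network, test: Arrays) -> ConfusionMatrix:
    """Tally argmax predictions on a split into TP/FP/TN/FN."""
    if len(test) == 0:
        raise ValueError("empty evaluation split")
    pred = predict(model, test)
    pos = 0  # PTH
    return ConfusionMatrix(
        TP=int(np.sum((pred == pos) & (test.y == pos))),
        FP=int(np.sum((pred == pos) & (test.y != pos))),
        TN=int(np.sum((pred != pos) & (test.y != pos))),
        FN=int(np.sum((pred != pos) & (test.y == pos))),
    )


def accuracy(cm: ConfusionMatrix) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    return (cm.TP + cm.TN) / cm.total


def evaluate_accuracy(model: Network, arrays: Arrays) -> float:
    return accuracy(confusion(model, arrays))


def aggregate(runs) -> tuple[float, float]:
    """Macro-averaged accuracy across runs: (mean, sample sd).

    A single run reports sd 0.0 (no dispersion observable).
    """
    runs = list(runs)
    if not runs:
        raise ValueError("no runs to aggregate")
    accs = np.array([r.accuracy if isinstance(r, RunReport) else float(r) for r in runs])
    sd = float(accs.std(ddof=1)) if len(accs) > 1 else 0.0
    return float(accs.mean()), sd


def run_training(
    spec: ArchitectureSpec,
    data: dict,
    config: TrainConfig,
) -> tuple[Network, RunReport]:
    """Build, train and evaluate one model; returns the fitted model and report."""
    t0 = time.perf_counter()
    model = build_model(spec, seed=config.seed)
    history = train(model, data, config)
    cm = confusion(model, data[TEST])
    report = RunReport(
        accuracy=accuracy(cm),
        confusion=cm,
        split_sizes={k: len(v) for k, v in data.items()},
        seed=config.seed,
        history=history,
        wall_time_s=time.perf_counter() - t0,
    )
    return model, report
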