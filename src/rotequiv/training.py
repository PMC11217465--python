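"""Training loop, learning curves, and the convergence-stability summary.

The reference protocol trains with Adam (learning rate 1e-5) on softmax
cross-entropy for a fixed number of epochs with no early stopping, recording
validation accuracy after every epoch. Convergence speed is summarized by a
stability metric: the *stable epoch* is the first epoch whose validation
accuracy reaches at least 95% of the run's highest accuracy; the accuracy and
cumulative wall-clock time at that epoch are the *stable accuracy* and the
*time until stability*. Wall-clock numbers are hardware dependent, so they
are recorded but analyses that must be reproducible compare epoch counts.

Desk-scale presets use a larger learning rate (1e-3) so that miniature
networks on miniature datasets converge within tens of epochs; everything
else follows the reference settings.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .architectures import ClassifierModel

__all__ = [
    "TrainingConfig",
    "EpochRecord",
    "LearningCurve",
    "StabilityMetrics",
    "train",
    "evaluate_accuracy",
    "stability_metrics",
    "desk_training_config",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings: cross-entropy loss, Adam optimizer."""

    learning_rate: float = 1e-5
    n_epochs: int = 100
    batch_size: int = 32
    seed: int = 0
    stability_fraction: float = 0.95

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0 < self.stability_fraction <= 1:
            raise ValueError("stability_fraction must be in (0, 1]")
        if self.n_epochs < 0:
            raise ValueError("n_epochs must be >= 0")


def desk_training_config(**overrides) -> TrainingConfig:
    """CPU-scale settings: fewer epochs, a practical small-net learning rate."""
    defaults = dict(learning_rate=1e-3, n_epochs=15, batch_size=16)
    defaults.update(overrides)
    return TrainingConfig(**defaults)


@dataclass(frozen=True)
class EpochRecord:
    epoch: int  # 1-based
    train_loss: float
    val_accuracy: float
    cum_seconds: float


@dataclass
class LearningCurve:
    """Per-epoch training record of one run."""

    records: list[EpochRecord] = field(default_factory=list)

    def __len__(self):
        return len(self.records)

    @property
    def val_accuracies(self) -> np.ndarray:
        return np.array([r.val_accuracy for r in self.records])

    @property
    def train_losses(self) -> np.ndarray:
        return np.array([r.train_loss for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LearningCurve":
        df = pd.read_csv(path)
        return cls([EpochRecord(int(r.epoch), float(r.train_loss),
                                float(r.val_accuracy), float(r.cum_seconds))
                    for r in df.itertuples()])


@dataclass(frozen=True)
class StabilityMetrics:
    """Top accuracy and the first epoch reaching >= fraction of it."""

    top_accuracy: float
    stable_epoch: int
    stable_accuracy: float
    time_until_stability: float


def stability_metrics(curve: LearningCurve, fraction: float = 0.95) -> StabilityMetrics:
    """Scan a learning curve for the convergence-stability summary.

    The stable epoch is the first whose validation accuracy is at least
    ``fraction`` times the curve's maximum ("at least 95%" by default, so
    ties at the threshold count).
    """
    if len(curve) == 0:
        raise ValueError("stability metrics need a nonempty learning curve")
    accs = curve.val_accuracies
    top = float(accs.max())
    threshold = fraction * top
    stable_idx = int(np.argmax(accs >= threshold))  # first True
    rec = curve.records[stable_idx]
    return StabilityMetrics(
        top_accuracy=top,
        stable_epoch=rec.epoch,
        stable_accuracy=float(rec.val_accuracy),
        time_until_stability=float(rec.cum_seconds),
    )


def evaluate_accuracy(model: ClassifierModel, x: np.ndarray, y: np.ndarray,
                      batch_size: int = 64) -> float:
    """Top-1 accuracy in eval mode (dropout off)."""
    correct = 0
    for start in range(0, len(x), batch_size):
        logits = model.forward(x[start : start + batch_size])
        correct += int((logits.argmax(axis=1) == y[start : start + batch_size]).sum())
    return correct / len(x)


def train(
    model: ClassifierModel,
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_x: np.ndarray,
    val_y: np.ndarray,
    config: TrainingConfig,
) -> tuple[LearningCurve, ClassifierModel]:
    """Train in place for exactly ``config.n_epochs`` epochs.

    Shuffling and dropout draw from one generator seeded by ``config.seed``,
    so a fixed seed reproduces the loss sequence exactly in single-threaded
    execution. Aborts with a diagnostic if the loss turns non-finite.
    """
    if len(train_x) == 0 or len(val_x) == 0:
        raise ValueError("training and validation sets must be nonempty")
    train_x = np.asarray(train_x, dtype=float)
    val_x = np.asarray(val_x, dtype=float)
    train_y = np.asarray(train_y)
    val_y = np.asarray(val_y)
    rng = np.random.default_rng(config.seed)
    optimizer = nn.Adam(model.net, lr=config.learning_rate)
    curve = LearningCurve()
    t0 = time.perf_counter()
    for epoch in range(1, config.n_epochs + 1):
        order = rng.permutation(len(train_x))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model.forward(train_x[idx], train=True, rng=rng)
            loss, grad = nn.softmax_cross_entropy(logits, train_y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {start // config.batch_size}"
                )
            model.net.backward(grad)
            optimizer.step()
            losses.append(loss)
        val_acc = evaluate_accuracy(model, val_x, val_y)
        curve.records.append(
            EpochRecord(epoch, float(np.mean(losses)), val_acc, time.perf_counter() - t0)
        )
    return curve, model


def save_run_metadata(path, *, training: TrainingConfig, extra: dict | None = None) -> None:
    """Write the run's configuration (and a stable hash of it) as JSON."""
    payload = {"training": asdict(training)}
    if extra:
        payload.update(extra)
    blob = json.dumps(payload, sort_keys=True)
    payload["config_hash"] = hashlib.sha1(blob.encode()).hexdigest()[:8]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
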