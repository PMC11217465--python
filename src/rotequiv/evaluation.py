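"""Confusion-matrix summaries, comparison arithmetic, and power-law scaling.

Classification quality is summarized from the multi-class confusion matrix
(rows = actual class, columns = predicted class) via one-vs-rest macro
sensitivity TP/(TP+FN) and specificity TN/(TN+FP), averaged unweighted over
classes (micro variants are provided alongside). Paired model comparisons
report the relative improvement 100*(new - baseline)/baseline in percent.

Data efficiency is modelled as a power law y = a * x**k between evaluation
error y and training-set size x; taking logarithms gives the linear model
log y = log a + k log x, fitted by ordinary least squares. A steeper
(more negative) exponent k means the model converts additional training
data into error reduction faster. :func:`run_scaling_experiment` orchestrates
the sweep: nested class-balanced subsamples per size, one training run per
(condition, size, seed), errors on a fixed held-out set, one fit per
condition on the per-size mean errors, with per-cell JSON caching so an
interrupted sweep resumes without retraining.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion

from .architectures import ArchitectureConfig, build_classifier
from .synthetic import ImageSample, samples_to_arrays, subsample_training
from .training import TrainingConfig, evaluate_accuracy, train

__all__ = [
    "ConfusionMatrix",
    "PowerLawFit",
    "ScalingExperimentResult",
    "confusion_matrix",
    "macro_sensitivity",
    "macro_specificity",
    "micro_sensitivity",
    "relative_improvement",
    "fit_power_law",
    "run_scaling_experiment",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """n x n count table; rows are actual classes, columns predictions."""

    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (counts < 0).any():
            raise ValueError("confusion matrix entries must be nonnegative")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.counts).to_csv(path, index=False)


def confusion_matrix(predictions, labels, n_classes: int) -> ConfusionMatrix:
    """Tally counts[i, j] = number of samples with actual i predicted j."""
    predictions = np.asarray(predictions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    for name, arr in (("predictions", predictions), ("labels", labels)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} contain classes outside 0..{n_classes - 1}")
    counts = _sk_confusion(labels, predictions, labels=np.arange(n_classes))
    return ConfusionMatrix(counts)


def _per_class_rates(cm: ConfusionMatrix):
    counts = cm.counts
    tp = np.diag(counts).astype(float)
    fn = counts.sum(axis=1) - tp
    fp = counts.sum(axis=0) - tp
    tn = cm.total - tp - fn - fp
    return tp, fn, fp, tn


def macro_sensitivity(cm: ConfusionMatrix) -> float:
    """Unweighted mean over classes of TP/(TP+FN) (one-vs-rest recall)."""
    tp, fn, _, _ = _per_class_rates(cm)
    actual = tp + fn
    if (actual == 0).any():
        empty = int(np.nonzero(actual == 0)[0][0])
        raise ValueError(f"class {empty} has no actual samples; sensitivity undefined")
    return float(np.mean(tp / actual))


def macro_specificity(cm: ConfusionMatrix) -> float:
    """Unweighted mean over classes of TN/(TN+FP)."""
    tp, fn, fp, tn = _per_class_rates(cm)
    negatives = tn + fp
    if (negatives == 0).any():
        empty = int(np.nonzero(negatives == 0)[0][0])
        raise ValueError(f"class {empty} has no negative samples; specificity undefined")
    return float(np.mean(tn / negatives))


def micro_sensitivity(cm: ConfusionMatrix) -> float:
    """Pooled TP/(TP+FN) over all classes (equals overall accuracy)."""
    tp, fn, _, _ = _per_class_rates(cm)
    return float(tp.sum() / (tp.sum() + fn.sum()))


def relative_improvement(new: float, baseline: float) -> float:
    """Percent change of ``new`` over ``baseline``: 100*(new-baseline)/baseline."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * (new - baseline) / baseline


@dataclass(frozen=True)
class PowerLawFit:
    """y = amplitude * x**exponent, fitted as a line in log-log space."""

    amplitude: float
    exponent: float
    log_amplitude: float
    residual_ss: float
    n_points: int

    def predict(self, x) -> np.ndarray:
        return self.amplitude * np.asarray(x, dtype=float) ** self.exponent


def fit_power_law(xs, ys) -> PowerLawFit:
    """OLS of log y on log x (natural logs; the slope is base-invariant)."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size != ys.size or xs.size < 2:
        raise ValueError("need at least two (x, y) pairs of equal length")
    if (xs <= 0).any() or (ys <= 0).any():
        raise ValueError("power-law fitting requires strictly positive x and y")
    if np.allclose(xs, xs[0]):
        raise ValueError("x values must not all be equal")
    lx, ly = np.log(xs), np.log(ys)
    res = stats.linregress(lx, ly)
    resid = ly - (res.intercept + res.slope * lx)
    return PowerLawFit(
        amplitude=float(np.exp(res.intercept)),
        exponent=float(res.slope),
        log_amplitude=float(res.intercept),
        residual_ss=float(np.sum(resid**2)),
        n_points=int(xs.size),
    )


@dataclass
class ScalingExperimentResult:
    """Per-cell end errors and one power-law fit per condition."""

    cells: pd.DataFrame  # columns: condition, size, seed, end_error, top_accuracy
    fits: dict[str, PowerLawFit] = field(default_factory=dict)
    failures: list[dict] = field(default_factory=list)

    def mean_errors(self, condition: str) -> pd.Series:
        sub = self.cells[self.cells["condition"] == condition]
        return sub.groupby("size")["end_error"].mean()

    def to_json(self, path) -> None:
        payload = {
            "fits": {
                name: {
                    "amplitude": f.amplitude,
                    "exponent": f.exponent,
                    "residual_ss": f.residual_ss,
                    "n_points": f.n_points,
                }
                for name, f in self.fits.items()
            },
            "failures": self.failures,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _cell_path(cache_dir: Path, condition: str, size: int, seed: int) -> Path:
    return cache_dir / f"cell_{condition}_{size}_{seed}.json"


def run_scaling_experiment(
    train_pool: list[ImageSample],
    eval_samples: list[ImageSample],
    model_configs: dict[str, ArchitectureConfig],
    sizes: list[int],
    seeds: list[int],
    training: TrainingConfig,
    cache_dir=None,
    error_from: str = "final",
) -> ScalingExperimentResult:
    """Sweep training-set size for each condition and fit one power law each.

    ``error_from`` selects the end error: "final" uses 1 - final-epoch
    accuracy on the held-out set, "best" uses 1 - best-epoch validation
    accuracy. Per-cell results are cached as JSON under ``cache_dir`` so a
    rerun with identical settings performs no training. A failed cell is
    recorded and skipped; the fit uses the remaining cells.
    """
    if sorted(sizes) != list(sizes) or len(set(sizes)) != len(sizes):
        raise ValueError("sizes must be strictly increasing")
    if max(sizes) > len(train_pool):
        raise ValueError(f"largest size {max(sizes)} exceeds pool of {len(train_pool)}")
    if error_from not in ("final", "best"):
        raise ValueError("error_from must be 'final' or 'best'")
    cache_dir = Path(cache_dir) if cache_dir is not None else None
    if cache_dir is not None:
        cache_dir.mkdir(parents=True, exist_ok=True)
    ex, ey = samples_to_arrays(eval_samples)
    rows, failures = [], []
    for condition, arch in model_configs.items():
        for size in sizes:
            for seed in seeds:
                cached = None
                if cache_dir is not None:
                    path = _cell_path(cache_dir, condition, size, seed)
                    if path.exists():
                        cached = json.loads(path.read_text())
                if cached is None:
                    try:
                        subset = subsample_training(train_pool, size, seed=seed)
                        sx, sy = samples_to_arrays(subset)
                        model = build_classifier(arch, seed=seed)
                        run_cfg = TrainingConfig(
                            learning_rate=training.learning_rate,
                            n_epochs=training.n_epochs,
                            batch_size=training.batch_size,
                            seed=seed,
                            stability_fraction=training.stability_fraction,
                        )
                        curve, model = train(model, sx, sy, ex, ey, run_cfg)
                        final_acc = evaluate_accuracy(model, ex, ey)
                        best_acc = float(curve.val_accuracies.max())
                        cached = {
                            "condition": condition,
                            "size": size,
                            "seed": seed,
                            "final_accuracy": final_acc,
                            "best_accuracy": best_acc,
                        }
                        if cache_dir is not None:
                            path.write_text(json.dumps(cached))
                    except Exception as exc:  # noqa: BLE001 — cell isolation
                        failures.append(
                            {"condition": condition, "size": size, "seed": seed,
                             "error": str(exc)}
                        )
                        continue
                acc = cached["final_accuracy" if error_from == "final" else "best_accuracy"]
                rows.append(
                    {
                        "condition": condition,
                        "size": size,
                        "seed": seed,
                        "end_error": 1.0 - acc,
                        "top_accuracy": cached["best_accuracy"],
                    }
                )
    cells = pd.DataFrame(rows, columns=["condition", "size", "seed", "end_error", "top_accuracy"])
    result = ScalingExperimentResult(cells=cells, failures=failures)
    floor = 1e-6  # a zero error cannot enter a log-log fit
    for condition in model_configs:
        means = result.mean_errors(condition)
        if len(means) >= 2:
            result.fits[condition] = fit_power_law(
                means.index.to_numpy(), np.maximum(means.to_numpy(), floor)
            )
    return result


def plot_scaling(result: ScalingExperimentResult, path) -> None:
    """Log-log plot of mean end error vs training size with fitted lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for condition, fit in result.fits.items():
        means = result.mean_errors(condition)
        ax.loglog(means.index, means.values, "o", label=f"{condition} (k={fit.exponent:.2f})")
        xs = np.linspace(means.index.min(), means.index.max(), 50)
        ax.loglog(xs, fit.predict(xs), "-", alpha=0.6)
    ax.set_xlabel("training samples")
    ax.set_ylabel("end error")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
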