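"""Training/evaluation protocol: repeated runs and comparison statistics.

The evaluation protocol re-splits and re-initializes on a fresh seed for
each of (by default) ten runs, reports calibration/validation/test
accuracies per run, and summarizes them per set. Comparison statistics
mirror the complexity/accuracy table of the model comparison: percentage
parameter reduction of the modified network and relative accuracy
improvement over the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .dataset_io import DatasetSplit, SplitSpec, stratified_split
from .nn import ResNet1D, TrainConfig, train_network
from .synthetic import SpectralDataset

__all__ = [
    "TrainConfig",
    "RunResult",
    "RepeatedRunSummary",
    "train",
    "accuracy",
    "repeated_runs",
    "parameter_reduction",
    "relative_accuracy_improvement",
]


@dataclass(frozen=True)
class RunResult:
    run_index: int
    calibration_accuracy: float
    validation_accuracy: float
    test_accuracy: float
    seeds: dict = field(default_factory=dict)

    def __post_init__(self):
        for a in (self.calibration_accuracy, self.validation_accuracy, self.test_accuracy):
            if not 0.0 <= a <= 1.0:
                raise ValueError("accuracies must lie in [0, 1]")


@dataclass(frozen=True)
class SetSummary:
    mean: float
    std: float
    min: float
    max: float


@dataclass(frozen=True)
class RepeatedRunSummary:
    calibration: SetSummary
    validation: SetSummary
    test: SetSummary

    @staticmethod
    def from_results(results: Sequence[RunResult]) -> "RepeatedRunSummary":
        def agg(vals):
            v = np.asarray(vals, dtype=float)
            return SetSummary(float(v.mean()), float(v.std(ddof=0)),
                              float(v.min()), float(v.max()))

        return RepeatedRunSummary(
            calibration=agg([r.calibration_accuracy for r in results]),
            validation=agg([r.validation_accuracy for r in results]),
            test=agg([r.test_accuracy for r in results]),
        )


def accuracy(predicted, truth) -> float:
    """Fraction of exact matches between two equal-length grade sequences."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape or predicted.size == 0:
        raise ValueError("sequences must be non-empty and of equal length")
    return float(np.mean(predicted == truth))


def train(
    net: ResNet1D,
    ds: SpectralDataset,
    split: DatasetSplit,
    cfg: TrainConfig,
) -> list[float]:
    """Train a network on the calibration view of a split, in place.

    Returns the per-epoch loss history (empty for zero epochs, in which
    case the network is untouched).
    """
    cal = split.calibration
    if len(cal) == 0:
        raise ValueError("calibration set is empty")
    X = ds.intensities[cal]
    _, y_idx = np.unique(ds.grades, return_inverse=True)
    return train_network(net, X, y_idx[cal], cfg)


def repeated_runs(
    model_builder: Callable[[int], object],
    dataset: SpectralDataset,
    split_spec: SplitSpec,
    n_runs: int = 10,
    base_seed: int = 0,
) -> tuple[list[RunResult], RepeatedRunSummary]:
    """Run the split/fit/evaluate protocol ``n_runs`` times.

    Run ``i`` re-splits and builds a fresh model with seed ``base_seed+i``,
    so different model families evaluated with the same builder signature
    and base seed see identical partitions (paired comparison).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    results = []
    for i in range(n_runs):
        seed = base_seed + i
        split = stratified_split(dataset, replace(split_spec, seed=seed))
        model = model_builder(seed)
        X, y = dataset.intensities, dataset.grades
        model.fit(X[split.calibration], y[split.calibration])
        accs = {}
        for name in DatasetSplit.SET_NAMES:
            idx = split.indices(name)
            accs[name] = accuracy(model.predict(X[idx]), y[idx])
        results.append(
            RunResult(
                run_index=i,
                calibration_accuracy=accs["calibration"],
                validation_accuracy=accs["validation"],
                test_accuracy=accs["test"],
                seeds={"split": seed, "model": seed},
            )
        )
    return results, RepeatedRunSummary.from_results(results)


def parameter_reduction(base_count: int, modified_count: int) -> float:
    """Percentage reduction (1 - modified/base) * 100, to 2 decimals."""
    if base_count <= 0:
        raise ValueError("base_count must be > 0")
    return round((1.0 - modified_count / base_count) * 100.0, 2)


def relative_accuracy_improvement(base_acc: float, new_acc: float) -> float:
    """Relative accuracy change (new - base)/base * 100, to 2 decimals."""
    if base_acc <= 0:
        raise ValueError("base_acc must be > 0")
    return round((new_acc - base_acc) / base_acc * 100.0, 2)
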