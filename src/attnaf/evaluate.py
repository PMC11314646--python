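"""Confusion-matrix metrics, per-dataset reports and the ablation harness.

AF is the positive class throughout.  Accuracy, sensitivity (true-positive
rate on AF), specificity (true-negative rate on non-AF) and F1 are reported
in percent to two decimals; a metric whose denominator is zero is reported
as missing (``None``), never as 0.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import RRWindow, ValidationError, windows_to_arrays
from .model_zoo import ModelConfig, TrainedModel
from .train import TrainConfig, train_model


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_matrix(self) -> np.ndarray:
        """Rows = true class (non-AF, AF); columns = predicted class."""
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])


def confusion(predictions, labels) -> ConfusionCounts:
    """Count TP/FP/TN/FN with AF (1) as the positive class."""
    predictions = np.asarray(predictions, dtype=np.int64)
    labels = np.asarray(labels, dtype=np.int64)
    if predictions.shape != labels.shape:
        raise ValidationError(f"length mismatch: {predictions.shape} vs {labels.shape}")
    if predictions.size and not (set(np.unique(predictions)) <= {0, 1}
                                 and set(np.unique(labels)) <= {0, 1}):
        raise ValidationError("predictions and labels must be binary (0/1)")
    return ConfusionCounts(
        tp=int(np.sum((predictions == 1) & (labels == 1))),
        fp=int(np.sum((predictions == 1) & (labels == 0))),
        tn=int(np.sum((predictions == 0) & (labels == 0))),
        fn=int(np.sum((predictions == 0) & (labels == 1))),
    )


def _pct(num: float, den: float) -> float | None:
    return round(100.0 * num / den, 2) if den else None


def metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Ac/Sen/Spec/F1 in percent (two decimals); undefined ratios are None."""
    if c.total == 0:
        raise ValidationError("empty confusion counts")
    return {
        "accuracy": _pct(c.tp + c.tn, c.total),
        "sensitivity": _pct(c.tp, c.tp + c.fn),
        "specificity": _pct(c.tn, c.tn + c.fp),
        "f1": _pct(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    }


@dataclass
class EvalReport:
    """Metrics + confusion counts for one model on one or more test sets."""

    model_id: str
    per_dataset: dict[str, dict] = field(default_factory=dict)

    def add(self, dataset: str, counts: ConfusionCounts) -> None:
        self.per_dataset[dataset] = {"counts": vars(counts).copy(), **metrics(counts)}

    def to_dict(self) -> dict:
        return {"model_id": self.model_id, "per_dataset": self.per_dataset}


def evaluate_model(model: TrainedModel, windows: list[RRWindow], dataset: str = "test",
                   model_id: str = "model") -> EvalReport:
    """Predict (argmax of softmax) on a window set and tabulate the metrics."""
    X, y = windows_to_arrays(windows)
    counts = confusion(model.predict(X), y)
    report = EvalReport(model_id=model_id)
    report.add(dataset, counts)
    return report


def accuracy(model: TrainedModel, windows: list[RRWindow]) -> float:
    X, y = windows_to_arrays(windows)
    return float((model.predict(X) == y).mean())


def ablation_suite(base_cfgs: list[ModelConfig], data_train: list[RRWindow],
                   data_tests: dict[str, list[RRWindow]], seeds: list[int],
                   train_cfg: TrainConfig | None = None) -> list[dict]:
    """Train each config and its attention-stripped twin on identical data/seeds.

    For every (config, test set) pair two rows are emitted — with and
    without the attention module — carrying the mean and per-seed accuracies
    over ``seeds``.  Row count is ``len(base_cfgs) * len(data_tests) * 2``.
    """
    if train_cfg is None:
        train_cfg = TrainConfig()
    rows: list[dict] = []
    for cfg in base_cfgs:
        if cfg.attention == "none":
            raise ValidationError("ablation needs configs with an attention module")
        for variant_cfg, tag in ((cfg, cfg.attention), (cfg.strip_attention(), "none")):
            accs_by_test: dict[str, list[float]] = {name: [] for name in data_tests}
            for seed in seeds:
                seeded = TrainConfig(learning_rate=train_cfg.learning_rate,
                                     batch_size=train_cfg.batch_size, epochs=train_cfg.epochs,
                                     momentum=train_cfg.momentum, seed=seed,
                                     shuffle_each_epoch=train_cfg.shuffle_each_epoch)
                model, _ = train_model(variant_cfg, data_train, seeded)
                for name, windows in data_tests.items():
                    accs_by_test[name].append(accuracy(model, windows))
            for name, accs in accs_by_test.items():
                rows.append({
                    "variant": variant_cfg.variant,
                    "activation": variant_cfg.activation,
                    "attention": tag,
                    "test_set": name,
                    "mean_accuracy": float(np.mean(accs)),
                    "per_seed_accuracy": [float(a) for a in accs],
                })
    return rows
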