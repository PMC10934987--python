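"""Evaluation of predicted label maps against ground truth."""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass

import numpy as np

from .hsi_io import LabelMap

__all__ = [
    "ConfusionMatrix",
    "confusion_matrix",
    "accuracy",
    "per_class_accuracy",
    "write_report",
]


@dataclass
class ConfusionMatrix:
    """Integer count matrix; rows index the true class, columns the predicted."""

    counts: np.ndarray  # (n_classes, n_classes) int
    n_total: int

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]


def confusion_matrix(truth: LabelMap, pred: LabelMap) -> ConfusionMatrix:
    if (truth.height, truth.width) != (pred.height, pred.width):
        raise ValueError(
            f"label maps disagree in shape: truth {truth.height}x{truth.width}, "
            f"pred {pred.height}x{pred.width}"
        )
    if truth.n_classes != pred.n_classes:
        raise ValueError(
            f"label maps disagree in n_classes: {truth.n_classes} vs {pred.n_classes}"
        )
    n = truth.n_classes
    counts = np.zeros((n, n), dtype=np.int64)
    np.add.at(counts, (truth.flat(), pred.flat()), 1)
    return ConfusionMatrix(counts=counts, n_total=truth.n_pixels)


def accuracy(cm: ConfusionMatrix) -> float:
    """Overall agreement, trace / total."""
    return float(np.trace(cm.counts)) / cm.n_total


def per_class_accuracy(cm: ConfusionMatrix) -> np.ndarray:
    """Diagonal over row sums; NaN (undefined, not zero) for absent classes."""
    row_sums = cm.counts.sum(axis=1)
    out = np.full(cm.n_classes, np.nan)
    present = row_sums > 0
    out[present] = np.diag(cm.counts)[present] / row_sums[present]
    return out


def write_report(cm: ConfusionMatrix, path: str | os.PathLike, fmt: str = "json") -> None:
    """Emit the confusion matrix and summary accuracies as JSON or CSV.

    Undefined per-class accuracies are emitted as null (JSON) or an
    empty cell (CSV).
    """
    per_class = per_class_accuracy(cm)
    if fmt == "json":
        doc = {
            "n_total": cm.n_total,
            "accuracy": accuracy(cm),
            "per_class_accuracy": [
                None if np.isnan(v) else float(v) for v in per_class
            ],
            "confusion_matrix": cm.counts.tolist(),
        }
        with open(os.fspath(path), "w") as fh:
            json.dump(doc, fh, indent=1)
    elif fmt == "csv":
        with open(os.fspath(path), "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["true\\pred"] + list(range(cm.n_classes)) + ["class_accuracy"])
            for t in range(cm.n_classes):
                acc = "" if np.isnan(per_class[t]) else f"{per_class[t]:.6f}"
                writer.writerow([t] + cm.counts[t].tolist() + [acc])
            writer.writerow(["overall", accuracy(cm)])
    else:
        raise ValueError(f"fmt must be 'json' or 'csv', got {fmt!r}")
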