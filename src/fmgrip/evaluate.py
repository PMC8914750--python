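"""Evaluation metrics: RMSE between measured and estimated grip force,
force-deformation correlation, confusion-matrix bookkeeping and the
per-angle experiment summary."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion

from .voigt import ANGLES, GripTrace

__all__ = ["rmse", "pearson_correlation", "ConfusionMatrix", "EvalSummary",
           "summarize_experiment"]


def rmse(Fm, Fp) -> float:
    """Root-mean-square error sqrt(mean((Fp - Fm)^2)), in newtons."""
    Fm = np.asarray(Fm, dtype=float)
    Fp = np.asarray(Fp, dtype=float)
    if Fm.shape != Fp.shape or Fm.size == 0:
        raise ValueError("Fm and Fp must be equal-length, non-empty")
    return float(np.sqrt(np.mean((Fp - Fm) ** 2)))


def pearson_correlation(x, y) -> float:
    """Product-moment correlation coefficient r in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("x and y must be equal-length with >= 3 samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class ConfusionMatrix:
    """3x3 counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: list = field(default_factory=lambda: list(ANGLES))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k) or np.any(self.counts < 0):
            raise ValueError("counts must be a non-negative square matrix")

    @classmethod
    def from_labels(cls, y_true, y_pred, classes=None) -> "ConfusionMatrix":
        classes = list(classes) if classes is not None else list(ANGLES)
        return cls(_sk_confusion(y_true, y_pred, labels=classes), classes)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total)

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        idx = [f"true_{c}" for c in self.classes]
        cols = [f"pred_{c}" for c in self.classes]
        return pd.DataFrame(self.counts, index=idx, columns=cols)

    def __str__(self) -> str:
        return self.to_frame().to_string()


@dataclass
class EvalSummary:
    """Per-angle RMSE summary with overall correlation and confusion."""

    rmse_per_angle: dict
    rmse_mean: float
    rmse_sd: float
    pearson_r: float
    confusion: ConfusionMatrix | None = None
    angle_accuracy: float | None = None

    def to_dict(self) -> dict:
        d = {
            "rmse_per_angle_N": {str(a): v for a, v in
                                 sorted(self.rmse_per_angle.items())},
            "rmse_mean_N": self.rmse_mean,
            "rmse_sd_N": self.rmse_sd,
            "pearson_r": self.pearson_r,
        }
        if self.confusion is not None:
            d["confusion"] = {"classes": self.confusion.classes,
                              "counts": self.confusion.counts.tolist()}
        if self.angle_accuracy is not None:
            d["angle_accuracy"] = self.angle_accuracy
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def summarize_experiment(traces: dict[int, list[GripTrace]],
                         confusion: ConfusionMatrix | None = None,
                         angle_accuracy: float | None = None) -> EvalSummary:
    """Aggregate per-angle grip traces into an EvalSummary.

    ``rmse_mean`` / ``rmse_sd`` are taken across all angle x replicate
    trace-level RMSEs; ``pearson_r`` correlates the concatenated measured
    and estimated force series.
    """
    missing = [a for a in ANGLES if a not in traces or not traces[a]]
    if missing:
        raise ValueError(f"missing traces for angles {missing}")
    per_trace = {a: [rmse(tr.Fm, tr.Fp) for tr in trs]
                 for a, trs in traces.items()}
    all_rmse = np.concatenate([np.asarray(v) for v in per_trace.values()])
    fm = np.concatenate([tr.Fm for trs in traces.values() for tr in trs])
    fp = np.concatenate([tr.Fp for trs in traces.values() for tr in trs])
    return EvalSummary(
        rmse_per_angle={a: float(np.mean(v)) for a, v in per_trace.items()},
        rmse_mean=float(all_rmse.mean()),
        rmse_sd=float(all_rmse.std(ddof=1)) if len(all_rmse) > 1 else 0.0,
        pearson_r=pearson_correlation(fm, fp),
        confusion=confusion,
        angle_accuracy=angle_accuracy,
    )
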