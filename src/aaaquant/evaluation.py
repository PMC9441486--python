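"""Segmentation metrics: confusion matrix, per-class report, corrections.

Per class, with TP/FP/FN pixel counts:

    precision = TP / (TP + FP)      recall = TP / (TP + FN)
    F1 = 2PR / (P + R)              Jaccard = TP / (TP + FP + FN)

F1 (identical to the DICE coefficient for sets) and Jaccard are related
by the exact identity ``J = F / (2 - F)``.

Two aggregation modes are provided: *macro* (unweighted mean over
classes) and *weighted* (support-weighted mean).  Aggregate Jaccard
values are obtained by converting the aggregated F1 through
``J = F / (2 - F)`` rather than averaging per-class Jaccards — the
convention under which the report aggregates are self-consistent; the
plain mean is available via ``jaccard_convention="mean"``.

Two corrections address artifacts of tile-level annotation:

* aggregates "excluding ignore" drop the ignore class entirely;
* :func:`correct_background` substitutes an estimated background
  precision (empty tiles mislabeled "ignore" in the ground truth
  depress the measured value) and recomputes the background F1/Jaccard
  and all aggregates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .classes import CLASS_ORDER
from .tiling import AnnotationMap

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "ClassReport",
    "confusion",
    "class_report",
    "aggregate",
    "correct_background",
    "jaccard_from_dice",
    "dice_from_jaccard",
]


def jaccard_from_dice(d: float | np.ndarray) -> float | np.ndarray:
    """Convert a DICE/F1 score to the equivalent Jaccard index: J = D/(2-D)."""
    d = np.asarray(d, dtype=float)
    if np.any((d < 0) | (d > 1)):
        raise ValueError("DICE score must lie in [0, 1]")
    out = d / (2.0 - d)
    return float(out) if out.ndim == 0 else out


def dice_from_jaccard(j: float | np.ndarray) -> float | np.ndarray:
    """Inverse conversion: D = 2J/(1+J)."""
    j = np.asarray(j, dtype=float)
    if np.any((j < 0) | (j > 1)):
        raise ValueError("Jaccard index must lie in [0, 1]")
    out = 2.0 * j / (1.0 + j)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ConfusionMatrix:
    """Pixel counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    class_order: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        c = len(self.class_order)
        if counts.shape != (c, c):
            raise ValueError(f"confusion matrix must be {c}x{c}")
        if np.any(counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def support(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def normalized(self) -> np.ndarray:
        """Row-normalized view (each true-class row sums to 1)."""
        rows = self.support.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.counts / rows[:, None]
        return np.nan_to_num(out)

    def to_frame(self, normalized: bool = False) -> pd.DataFrame:
        data = self.normalized() if normalized else self.counts
        return pd.DataFrame(data, index=list(self.class_order),
                            columns=list(self.class_order))

    def to_csv(self, path: str | Path, normalized: bool = False) -> None:
        self.to_frame(normalized).to_csv(path)

    def plot(self, path: str | Path | None = None):
        """Row-normalized confusion-matrix heatmap."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4.5))
        norm = self.normalized()
        im = ax.imshow(norm, cmap="viridis", vmin=0, vmax=1)
        ax.set_xticks(range(len(self.class_order)), self.class_order, rotation=45)
        ax.set_yticks(range(len(self.class_order)), self.class_order)
        ax.set_xlabel("predicted label")
        ax.set_ylabel("true label")
        for i in range(norm.shape[0]):
            for j in range(norm.shape[1]):
                ax.text(j, i, f"{norm[i, j]:.2f}", ha="center", va="center",
                        color="w" if norm[i, j] < 0.6 else "k", fontsize=8)
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


def confusion(pred: AnnotationMap | np.ndarray, truth: AnnotationMap | np.ndarray,
              class_order: tuple[str, ...] | None = None) -> ConfusionMatrix:
    """Confusion matrix between predicted and true label rasters."""
    if isinstance(pred, AnnotationMap):
        class_order = class_order or pred.class_order
        pred = pred.labels
    if isinstance(truth, AnnotationMap):
        class_order = class_order or truth.class_order
        truth = truth.labels
    class_order = class_order or CLASS_ORDER
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    c = len(class_order)
    counts = np.bincount(
        truth.ravel().astype(np.int64) * c + pred.ravel().astype(np.int64),
        minlength=c * c,
    ).reshape(c, c)
    return ConfusionMatrix(counts, class_order)


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    jaccard: float
    support: int


@dataclass(frozen=True)
class ClassReport:
    """Per-class precision/recall/F1/Jaccard/support."""

    per_class: dict[str, ClassMetrics]
    jaccard_convention: str = "f1"  # aggregate J from aggregate F1; or "mean"

    @property
    def class_order(self) -> tuple[str, ...]:
        return tuple(self.per_class)

    def to_frame(self, corrected_bg_label: str | None = None,
                 include_aggregates: bool = True) -> pd.DataFrame:
        rows, index = [], []
        for name, m in self.per_class.items():
            index.append(corrected_bg_label if corrected_bg_label and name == "background" else name)
            rows.append([m.precision, m.recall, m.f1, m.jaccard, m.support])
        if include_aggregates:
            for mode in ("macro", "weighted"):
                agg = aggregate(self, mode)
                index.append(f"{mode} avg")
                rows.append([agg.precision, agg.recall, agg.f1, agg.jaccard, agg.support])
            if "ignore" in self.per_class:
                for mode in ("macro", "weighted"):
                    agg = aggregate(self, mode, exclude={"ignore"})
                    index.append(f"{mode} avg (excl. ignore)")
                    rows.append([agg.precision, agg.recall, agg.f1, agg.jaccard, agg.support])
        return pd.DataFrame(
            rows, index=index,
            columns=["Precision", "Recall", "F1-score", "Jaccard index", "Support"],
        )

    def to_csv(self, path: str | Path, decimals: int = 3) -> None:
        frame = self.to_frame()
        metric_cols = frame.columns[:-1]
        frame[metric_cols] = frame[metric_cols].round(decimals)
        frame["Support"] = frame["Support"].astype(np.int64)
        frame.to_csv(path)


def _metrics_from_counts(tp: float, fp: float, fn: float, support: int) -> ClassMetrics:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    jaccard = tp / (tp + fp + fn) if tp + fp + fn else 0.0
    return ClassMetrics(precision, recall, f1, jaccard, support)


def class_report(cm: ConfusionMatrix) -> ClassReport:
    """Per-class metrics from a confusion matrix (zero-denominators -> 0)."""
    tp = cm.counts.diagonal().astype(float)
    support = cm.support
    predicted = cm.counts.sum(axis=0).astype(float)
    per_class = {}
    for i, name in enumerate(cm.class_order):
        per_class[name] = _metrics_from_counts(
            tp[i], predicted[i] - tp[i], support[i] - tp[i], int(support[i])
        )
    return ClassReport(per_class)


def aggregate(report: ClassReport, mode: str = "macro",
              exclude: set[str] | frozenset[str] = frozenset()) -> ClassMetrics:
    """Aggregate a report's per-class rows.

    ``mode`` is "macro" (unweighted) or "weighted" (support-weighted).
    Precision, recall and F1 are averaged directly; the aggregate
    Jaccard follows the report's convention (default: J = F/(2-F) on
    the aggregated F1).  Zero-support classes are dropped from macro
    averages with a warning.
    """
    if mode not in ("macro", "weighted"):
        raise ValueError("mode must be 'macro' or 'weighted'")
    names = [n for n in report.per_class if n not in exclude]
    if not names:
        raise ValueError("no classes left to aggregate")
    zero = [n for n in names if report.per_class[n].support == 0]
    if zero:
        warnings.warn(f"dropping zero-support classes from aggregate: {zero}")
        names = [n for n in names if n not in zero]
        if not names:
            raise ValueError("all included classes have zero support")
    metrics = [report.per_class[n] for n in names]
    supports = np.array([m.support for m in metrics], dtype=float)
    w = supports / supports.sum() if mode == "weighted" else np.full(len(metrics), 1.0 / len(metrics))
    precision = float(np.dot(w, [m.precision for m in metrics]))
    recall = float(np.dot(w, [m.recall for m in metrics]))
    f1 = float(np.dot(w, [m.f1 for m in metrics]))
    if report.jaccard_convention == "f1":
        jaccard = jaccard_from_dice(f1)
    else:
        jaccard = float(np.dot(w, [m.jaccard for m in metrics]))
    return ClassMetrics(precision, recall, f1, jaccard, int(supports.sum()))


def correct_background(report: ClassReport, estimated_bg_precision: float,
                       background: str = "background") -> ClassReport:
    """Substitute an estimated background precision and recompute.

    The background F1 is recomputed from the estimate and the original
    recall, the background Jaccard via J = F/(2-F); aggregates computed
    from the returned report reflect the substitution.
    """
    if not 0.0 < estimated_bg_precision <= 1.0:
        raise ValueError("estimated precision must be in (0, 1]")
    if background not in report.per_class:
        raise ValueError(f"no class named {background!r} in the report")
    old = report.per_class[background]
    p, r = estimated_bg_precision, old.recall
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    corrected = ClassMetrics(p, r, f1, jaccard_from_dice(f1), old.support)
    per_class = dict(report.per_class)
    per_class[background] = corrected
    return replace(report, per_class=per_class)
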