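"""Segmentation metrics from per-class pixel confusion counts.

Every metric derives from one-vs-rest pixel tallies per class:

    DSC       = 2 TP / (2 TP + FP + FN)
    IoU       = TP / (TP + FP + FN)          ( = DSC / (2 - DSC) )
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)

Dataset-level metrics pool confusion counts over all images (micro per
class), then macro-average across classes; classes absent from both
prediction and truth (TP+FP+FN = 0) are excluded from the macro means.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ConfusionCounts", "MetricReport", "confusion",
           "dsc", "iou", "precision", "recall", "evaluate_dataset"]


@dataclass
class ConfusionCounts:
    """Per-class TP/FP/FN/TN pixel counts (integer arrays of length K)."""
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    n_images: int = 1

    @property
    def num_classes(self) -> int:
        return len(self.tp)

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        if self.num_classes != other.num_classes:
            raise ValueError("class-count mismatch")
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn,
                               self.n_images + other.n_images)

    @staticmethod
    def zeros(k: int) -> "ConfusionCounts":
        z = np.zeros(k, dtype=np.int64)
        return ConfusionCounts(z.copy(), z.copy(), z.copy(), z.copy(), n_images=0)


def confusion(pred, truth, num_classes: int) -> ConfusionCounts:
    """One-vs-rest pixel confusion counts for a predicted/true label-map pair."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    for name, arr in (("pred", pred), ("truth", truth)):
        if arr.min() < 0 or arr.max() >= num_classes:
            raise ValueError(f"{name} labels outside [0, {num_classes})")
    k = num_classes
    cm = np.bincount(truth.ravel().astype(np.int64) * k + pred.ravel(),
                     minlength=k * k).reshape(k, k)
    tp = np.diag(cm).copy()
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = pred.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full_like(num, np.nan, dtype=float)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def dsc(c: ConfusionCounts) -> np.ndarray:
    return _safe_div(2.0 * c.tp, 2.0 * c.tp + c.fp + c.fn)


def iou(c: ConfusionCounts) -> np.ndarray:
    return _safe_div(c.tp.astype(float), c.tp + c.fp + c.fn)


def precision(c: ConfusionCounts) -> np.ndarray:
    return _safe_div(c.tp.astype(float), c.tp + c.fp)


def recall(c: ConfusionCounts) -> np.ndarray:
    return _safe_div(c.tp.astype(float), c.tp + c.fn)


@dataclass
class MetricReport:
    counts: ConfusionCounts
    class_names: list[str] | None = None
    per_class: pd.DataFrame = field(init=False)

    def __post_init__(self):
        k = self.counts.num_classes
        names = self.class_names or [f"class_{c}" for c in range(k)]
        self.per_class = pd.DataFrame({
            "class": names,
            "dsc": dsc(self.counts),
            "iou": iou(self.counts),
            "precision": precision(self.counts),
            "recall": recall(self.counts),
        })

    def _included(self, include_background: bool) -> np.ndarray:
        c = self.counts
        mask = (c.tp + c.fp + c.fn) > 0    # drop classes absent everywhere
        if not include_background:
            mask = mask.copy()
            mask[0] = False
        return mask

    def macro(self, metric: str, include_background: bool = True) -> float:
        """Macro mean of ``metric`` over included classes."""
        vals = self.per_class[metric].to_numpy()
        mask = self._included(include_background)
        if not mask.any():
            return float("nan")
        return float(np.nanmean(vals[mask]))

    def summary(self) -> dict:
        out = {"n_images": self.counts.n_images}
        for m in ("dsc", "iou", "precision", "recall"):
            out[f"macro_{m}"] = self.macro(m, include_background=True)
            out[f"macro_{m}_foreground"] = self.macro(m, include_background=False)
        return out

    def write(self, csv_path: str | Path, json_path: str | Path | None = None) -> None:
        csv_path = Path(csv_path)
        csv_path.parent.mkdir(parents=True, exist_ok=True)
        self.per_class.to_csv(csv_path, index=False)
        if json_path is not None:
            Path(json_path).write_text(json.dumps(self.summary(), indent=2))


def evaluate_dataset(model, samples, num_classes: int = 11, batch_size: int = 4,
                     class_names: list[str] | None = None) -> MetricReport:
    """Pooled confusion counts over a dataset of :class:`~hasaseg.data_io.Sample`.

    Predictions come from ``predict_mask`` on batches; counts accumulate
    across images before any ratio is formed, so the result equals the
    metrics of the pooled pixel population (not a mean of per-image scores).
    """
    from .network import predict_mask

    samples = list(samples)
    if not samples:
        raise ValueError("empty dataset")
    total = ConfusionCounts.zeros(num_classes)
    for i in range(0, len(samples), batch_size):
        chunk = samples[i:i + batch_size]
        images = np.stack([s.image for s in chunk])
        preds = predict_mask(model, images)
        for pred, s in zip(preds, chunk):
            total = total + confusion(pred, s.mask, num_classes)
    return MetricReport(total, class_names=class_names)
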