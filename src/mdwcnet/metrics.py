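"""Pixel-level binary segmentation metrics and their dataset aggregation.

Four standard quantities, all derived from per-image confusion counts with
foreground as the positive class:

* global pixel accuracy  (TP + TN) / (TP + FP + FN + TN)
* Dice coefficient       2 TP / (2 TP + FP + FN)
* mean IoU               average over {background, foreground} of
                         TP_i / (TP_i + FP_i + FN_i)
* sensitivity            TP / (TP + FN)

Metrics are computed per image and then averaged (mean +/- sample standard
deviation over images, reported in percent), not pooled over pixels, so the
spread reflects inter-image variability.  When a class is absent from both
prediction and reference, its overlap score (Dice, IoU) is defined as 1.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InvalidInputError


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Per-pixel confusion tally of two binary masks (1 = foreground)."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise InvalidInputError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    if not (np.isin(pred, (0, 1)).all() and np.isin(gt, (0, 1)).all()):
        raise InvalidInputError("masks must contain only {0, 1}")
    p = pred.astype(bool)
    g = gt.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & g)),
        fp=int(np.count_nonzero(p & ~g)),
        tn=int(np.count_nonzero(~p & ~g)),
        fn=int(np.count_nonzero(~p & g)),
    )


def gpa(c: ConfusionCounts) -> float:
    """Global pixel accuracy."""
    if c.total == 0:
        raise InvalidInputError("empty masks")
    return (c.tp + c.tn) / c.total


def dice(c: ConfusionCounts) -> float:
    """Dice coefficient; 1.0 when both masks lack foreground entirely."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return 2 * c.tp / denom


def miou(c_per_class: list[ConfusionCounts]) -> float:
    """Mean over classes of one-vs-rest IoU; absent classes score 1."""
    if not c_per_class:
        raise InvalidInputError("need at least one class")
    ious = []
    for c in c_per_class:
        denom = c.tp + c.fp + c.fn
        ious.append(1.0 if denom == 0 else c.tp / denom)
    return float(np.mean(ious))


def sensitivity(c: ConfusionCounts) -> float:
    """Foreground recall; undefined (error) when the reference is empty."""
    if c.tp + c.fn == 0:
        raise InvalidInputError("sensitivity undefined: no foreground in reference mask")
    return c.tp / (c.tp + c.fn)


def _background_counts(c: ConfusionCounts) -> ConfusionCounts:
    # one-vs-rest counts for class 0 are the complement of class 1's
    return ConfusionCounts(tp=c.tn, fp=c.fn, tn=c.tp, fn=c.fp)


def image_metrics(pred: np.ndarray, gt: np.ndarray) -> dict[str, float]:
    """All four metrics for one mask pair, as fractions in [0, 1]."""
    c = confusion_counts(pred, gt)
    return {
        "gpa": gpa(c),
        "dice": dice(c),
        "miou": miou([_background_counts(c), c]),
        "sensitivity": sensitivity(c),
    }


@dataclasses.dataclass
class MetricReport:
    """Mean +/- sample std over test images, in percent."""

    mean: dict[str, float]
    std: dict[str, float]
    per_image: list[dict[str, float]]
    ids: list[str]

    METRICS = ("gpa", "dice", "miou", "sensitivity")

    def summary(self) -> dict[str, str]:
        return {m: f"{self.mean[m]:.2f} ± {self.std[m]:.3f}" for m in self.METRICS}

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps({"mean": self.mean, "std": self.std, "formatted": self.summary()}, indent=2)
        )

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as f:
            wr = csv.writer(f)
            wr.writerow(["id", *self.METRICS])
            for i, row in zip(self.ids, self.per_image):
                wr.writerow([i] + [f"{row[m] * 100:.4f}" for m in self.METRICS])
            wr.writerow(["mean"] + [f"{self.mean[m]:.4f}" for m in self.METRICS])
            wr.writerow(["std"] + [f"{self.std[m]:.4f}" for m in self.METRICS])


def evaluate_dataset(preds, gts, ids=None) -> MetricReport:
    """Per-image metrics, aggregated as mean and sample (n-1) std, percent."""
    preds, gts = list(preds), list(gts)
    if not preds or len(preds) != len(gts):
        raise InvalidInputError("prediction and reference sequences must be equal-length and non-empty")
    per_image = [image_metrics(p, g) for p, g in zip(preds, gts)]
    ids = list(ids) if ids is not None else [str(i) for i in range(len(preds))]
    mean, std = {}, {}
    for m in MetricReport.METRICS:
        vals = np.array([row[m] for row in per_image]) * 100.0
        mean[m] = float(vals.mean())
        std[m] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return MetricReport(mean=mean, std=std, per_image=per_image, ids=ids)


def paired_t_test(a, b) -> float:
    """Two-sided p-value of the paired t-test on per-image metric vectors."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise InvalidInputError("need two equal-length vectors with n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise DegenerateInputError("paired differences have zero variance")
    return float(stats.ttest_rel(a, b).pvalue)
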