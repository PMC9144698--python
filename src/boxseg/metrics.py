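"""Segmentation evaluation: dice coefficient, pixel accuracy, confusion counts.

Metrics are computed per image and averaged arithmetically across images
(not pooled over pixels), which is why averaged confusion-matrix entries can
be fractional while still summing to the per-image pixel count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .domain import AnnotatedImage, validate_binary_mask

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "dice",
    "pixel_accuracy",
    "evaluate_masks",
    "evaluate_set",
    "two_sample_ttest",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: float
    tn: float
    fp: float
    fn: float

    @property
    def total(self) -> float:
        return self.tp + self.tn + self.fp + self.fn


def _check_pair(pred: np.ndarray, truth: np.ndarray) -> tuple:
    pred = validate_binary_mask(pred)
    truth = validate_binary_mask(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"mask shape mismatch: {pred.shape} vs {truth.shape}")
    return pred, truth


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    pred, truth = _check_pair(pred, truth)
    p = pred.astype(bool)
    t = truth.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
    )


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """2|A∩B| / (|A|+|B|); 1.0 by convention when both masks are empty."""
    pred, truth = _check_pair(pred, truth)
    inter = int(np.count_nonzero(pred.astype(bool) & truth.astype(bool)))
    size = int(pred.sum()) + int(truth.sum())
    if size == 0:
        return 1.0
    return 2.0 * inter / size


def pixel_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    pred, truth = _check_pair(pred, truth)
    return float(np.count_nonzero(pred == truth)) / pred.size


def _sem(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return 0.0
    return float(values.std(ddof=1) / np.sqrt(values.size))


def evaluate_masks(preds: Sequence[np.ndarray], truths: Sequence[np.ndarray]) -> dict:
    """Per-image dice/accuracy/confusion for aligned mask lists, averaged."""
    if len(preds) != len(truths) or len(preds) == 0:
        raise ValueError("need equally many (and at least one) predictions and truths")
    dices, accs, confs = [], [], []
    for p, t in zip(preds, truths):
        dices.append(dice(p, t))
        accs.append(pixel_accuracy(p, t))
        confs.append(confusion_counts(p, t))
    mean_conf = ConfusionCounts(
        tp=float(np.mean([c.tp for c in confs])),
        tn=float(np.mean([c.tn for c in confs])),
        fp=float(np.mean([c.fp for c in confs])),
        fn=float(np.mean([c.fn for c in confs])),
    )
    return {
        "mean_dice": float(np.mean(dices)),
        "sem_dice": _sem(np.array(dices)),
        "mean_accuracy": float(np.mean(accs)),
        "sem_accuracy": _sem(np.array(accs)),
        "mean_confusion": mean_conf,
        "per_image_dice": [float(d) for d in dices],
        "per_image_accuracy": [float(a) for a in accs],
    }


def evaluate_set(
    model,
    images: Sequence[AnnotatedImage],
    threshold: float = 0.5,
    tag: Optional[str] = None,
) -> dict:
    """Score a model against ground-truth masks of a set of images.

    ``model`` must expose ``predict_proba(image) -> probability map``.
    ``tag`` restricts evaluation to images carrying that tag (subset
    analysis, e.g. a difficult polyp class).
    """
    if tag is not None:
        images = [im for im in images if tag in im.tags]
    if not images:
        raise ValueError("no images to evaluate" + (f" with tag {tag!r}" if tag else ""))
    for im in images:
        if im.gt_mask is None:
            raise ValueError(f"{im.image_id}: evaluation requires gt_mask")
    preds = [(model.predict_proba(im) > threshold).astype(np.uint8) for im in images]
    truths = [im.gt_mask for im in images]
    report = evaluate_masks(preds, truths)
    report["n_images"] = len(images)
    report["per_image"] = [
        {"image_id": im.image_id, "dice": d, "accuracy": a}
        for im, d, a in zip(images, report["per_image_dice"], report["per_image_accuracy"])
    ]
    return report


def two_sample_ttest(scores_a: Sequence[float], scores_b: Sequence[float]) -> dict:
    """Plain two-sample t-test on per-fold scores (model comparison)."""
    t, p = stats.ttest_ind(np.asarray(scores_a, float), np.asarray(scores_b, float))
    return {"t_statistic": float(t), "p_value": float(p)}
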