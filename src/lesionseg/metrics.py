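"""Segmentation losses and evaluation metrics.

Training objective: hybrid loss = w_dice * (1 - soft Dice) + w_bce * BCE,
with soft Dice computed on probabilities with additive smoothing 1 and the
probabilities clipped to [1e-7, 1 - 1e-7] inside the BCE term.

Evaluation: Dice 2|A∩B|/(|A|+|B|), IoU |A∩B|/|A∪B| (= DC/(2-DC)), pixel
accuracy, precision, recall and ROC AUC, with lesion the positive class.
Dice/IoU are averaged per image; PA/precision/recall/AUC pool pixels across
the evaluation set (both conventions are exposed).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from sklearn.metrics import roc_auc_score

from . import autodiff as ad

__all__ = [
    "ConfusionCounts", "MetricsReport", "confusion", "dice", "iou",
    "basic_rates", "auc", "hybrid_loss", "hybrid_loss_tensor", "evaluate",
]

_CLIP = 1e-7
_SMOOTH = 1.0


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


@dataclass
class MetricsReport:
    dice: float
    iou: float
    pixel_accuracy: float
    precision: float
    recall: float
    auc: float
    counts: ConfusionCounts
    aggregation: str = "per-image-mean Dice/IoU, pooled rates"
    n_images: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["counts"] = asdict(self.counts)
        return d


def _as_binary(mask, name):
    mask = np.asarray(mask)
    binary = mask > 0 if mask.dtype != bool else mask
    return binary


def confusion(pred, truth) -> ConfusionCounts:
    """Pixelwise confusion counts with lesion (nonzero) as positive class."""
    pred = _as_binary(pred, "pred")
    truth = _as_binary(truth, "truth")
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return ConfusionCounts(tp, fp, fn, tn)


def dice(pred, truth) -> float:
    """Dice coefficient 2|A∩B|/(|A|+|B|); 1.0 when both masks are empty."""
    c = confusion(pred, truth)
    denom = 2 * c.tp + c.fp + c.fn
    return 1.0 if denom == 0 else 2.0 * c.tp / denom


def iou(pred, truth) -> float:
    """Jaccard index |A∩B|/|A∪B|; 1.0 when both masks are empty."""
    c = confusion(pred, truth)
    denom = c.tp + c.fp + c.fn
    return 1.0 if denom == 0 else c.tp / denom


def basic_rates(counts: ConfusionCounts):
    """(pixel_accuracy, precision, recall); zero-denominator cases return 1.0
    when the corresponding error count is also 0, else 0.0."""
    if min(counts.tp, counts.fp, counts.fn, counts.tn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    total = counts.total
    pa = (counts.tp + counts.tn) / total if total else 1.0
    if counts.tp + counts.fp == 0:
        precision = 1.0 if counts.fn == 0 else 0.0
    else:
        precision = counts.tp / (counts.tp + counts.fp)
    if counts.tp + counts.fn == 0:
        recall = 1.0 if counts.fp == 0 else 0.0
    else:
        recall = counts.tp / (counts.tp + counts.fn)
    return pa, precision, recall


def auc(probabilities, truth) -> Optional[float]:
    """Pooled-pixel ROC AUC via the midrank (Mann-Whitney) statistic.

    Returns None when the truth contains a single class (AUC undefined);
    callers exclude such images from aggregation.
    """
    p = np.asarray(probabilities, dtype=np.float64).ravel()
    t = _as_binary(truth, "truth").ravel()
    if p.shape != t.shape:
        raise ValueError("probabilities and truth differ in size")
    if t.all() or not t.any():
        return None
    return float(roc_auc_score(t.astype(np.int8), p))


def hybrid_loss(probabilities, truth, w_dice: float = 0.5,
                w_bce: float = 0.5) -> float:
    """Weighted sum of soft-Dice loss and mean binary cross-entropy."""
    if w_dice < 0 or w_bce < 0:
        raise ValueError("loss weights must be nonnegative")
    p = np.clip(np.asarray(probabilities, dtype=np.float64), _CLIP, 1 - _CLIP)
    t = _as_binary(truth, "truth").astype(np.float64)
    if p.shape != t.shape:
        raise ValueError("probabilities and truth differ in shape")
    inter = (p * t).sum()
    soft_dice = (2 * inter + _SMOOTH) / (p.sum() + t.sum() + _SMOOTH)
    bce = -(t * np.log(p) + (1 - t) * np.log(1 - p)).mean()
    return float(w_dice * (1.0 - soft_dice) + w_bce * bce)


def hybrid_loss_tensor(p: "ad.Tensor", truth: np.ndarray,
                       w_dice: float = 0.5, w_bce: float = 0.5) -> "ad.Tensor":
    """Differentiable hybrid loss on an autodiff probability tensor."""
    if w_dice < 0 or w_bce < 0:
        raise ValueError("loss weights must be nonnegative")
    t = ad.Tensor(np.asarray(truth, dtype=np.float32))
    pc = ad.clip(p, _CLIP, 1.0 - _CLIP)
    one = ad.Tensor(np.float32(1.0))
    inter = ad.tsum(ad.mul(pc, t))
    two_inter = ad.add(ad.mul(ad.Tensor(np.float32(2.0)), inter),
                       ad.Tensor(np.float32(_SMOOTH)))
    denom = ad.add(ad.add(ad.tsum(pc), ad.tsum(t)),
                   ad.Tensor(np.float32(_SMOOTH)))
    dice_loss = ad.sub(one, ad.div(two_inter, denom))
    bce = ad.tmean(ad.sub(ad.Tensor(np.float32(0.0)),
                          ad.add(ad.mul(t, ad.log(pc)),
                                 ad.mul(ad.sub(one, t),
                                        ad.log(ad.sub(one, pc))))))
    return ad.add(ad.mul(ad.Tensor(np.float32(w_dice)), dice_loss),
                  ad.mul(ad.Tensor(np.float32(w_bce)), bce))


def evaluate(model, images, masks, threshold: float = 0.5,
             batch_size: int = 8) -> MetricsReport:
    """Evaluate a model over a set of images with ground truth.

    ``images``: (N, H, W, 3) float array in [0,1]; ``masks``: (N, H, W)
    binary.  Dice/IoU are per-image means; PA/precision/recall/AUC are
    pooled across all pixels.  Images whose truth holds a single class are
    excluded from the per-image AUC pool only if pooling itself is
    single-class (then AUC is reported as nan).
    """
    images = np.asarray(images)
    masks = np.asarray(masks)
    if len(images) == 0:
        raise ValueError("empty evaluation set")
    probs = model.predict(images, batch_size=batch_size)
    dices, ious = [], []
    counts = ConfusionCounts(0, 0, 0, 0)
    for p, t in zip(probs, masks):
        pred = p >= threshold
        dices.append(dice(pred, t))
        ious.append(iou(pred, t))
        counts = counts + confusion(pred, t)
    pa, prec, rec = basic_rates(counts)
    pooled_auc = auc(probs, masks)
    return MetricsReport(
        dice=float(np.mean(dices)), iou=float(np.mean(ious)),
        pixel_accuracy=pa, precision=prec, recall=rec,
        auc=float("nan") if pooled_auc is None else pooled_auc,
        counts=counts, n_images=len(images))
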