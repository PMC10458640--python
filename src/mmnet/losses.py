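"""Hybrid binary cross-entropy + soft intersection-over-union objective.

The training loss is the unweighted sum of two terms.  With R the {0,1}
ground-truth label of pixel (e, p) and R-hat the predicted foreground
probability:

* BCE:  -sum_{e,p} [ R log R-hat + (1 - R) log(1 - R-hat) ]
* IoU:  1 - sum(R * R-hat) / sum(R + R-hat - R * R-hat)

BCE scores each pixel independently; the soft IoU term is a single global
ratio, so it couples all pixels and counteracts the background dilution BCE
suffers on images where the polyp occupies a small fraction of the frame.

Two reductions are provided.  ``"sum"`` is the literal printed form above
(per image; summed over a batch).  ``"mean"`` — the default used for
optimization — averages BCE per pixel and the IoU term per image, which keeps
gradient magnitudes independent of image size and batch size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

EPS = 1e-7


@dataclass(frozen=True)
class LossValue:
    """The two loss components and their sum (`total == bce + iou`)."""

    bce: float
    iou: float
    total: float
    graph: Tensor | None = None  # scalar autodiff node for backward()


def _prepare(pred, gt):
    pred_t = pred if isinstance(pred, Tensor) else Tensor(pred)
    gt_a = gt.data if isinstance(gt, Tensor) else np.asarray(gt, dtype=np.float64)
    if pred_t.data.shape != gt_a.shape:
        raise ValueError(
            f"shape mismatch: pred {pred_t.data.shape} vs gt {gt_a.shape}")
    vals = np.unique(gt_a)
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise ValueError("ground truth must be binary {0, 1}")
    return pred_t, gt_a


def _flatten_images(t: Tensor, gt: np.ndarray):
    """View pred/gt as (n_images, n_pixels)."""
    if t.data.ndim <= 2:
        return ad.reshape(t, (1, -1)), gt.reshape(1, -1)
    n = t.data.shape[0]
    return ad.reshape(t, (n, -1)), gt.reshape(n, -1)


def bce_loss(pred, gt, reduction: str = "sum") -> Tensor:
    """Pixelwise binary cross entropy; probabilities are clamped to [EPS, 1-EPS]."""
    pred_t, gt_a = _prepare(pred, gt)
    p = ad.clamp(pred_t, EPS, 1.0 - EPS)
    ll = ad.add(ad.mul(Tensor(gt_a), ad.log(p)),
                ad.mul(Tensor(1.0 - gt_a), ad.log(ad.add(ad.mul(p, -1.0), 1.0))))
    if reduction == "sum":
        return ad.mul(ad.tsum(ll), -1.0)
    if reduction == "mean":
        return ad.mul(ad.tmean(ll), -1.0)
    raise ValueError(f"unknown reduction {reduction!r}")


def iou_loss(pred, gt, reduction: str = "sum") -> Tensor:
    """Soft IoU loss, 1 - intersection/union, computed per image.

    For an all-background ground truth with an all-zero prediction the ratio
    is 0/0; the loss is 0 by convention (perfect) and a warning is issued.
    """
    pred_t, gt_a = _prepare(pred, gt)
    p2, g2 = _flatten_images(pred_t, gt_a)
    inter = ad.tsum(ad.mul(p2, Tensor(g2)), axis=1)
    union = ad.add(ad.tsum(p2, axis=1),
                   ad.tsum(ad.mul(ad.mul(p2, Tensor(g2)), -1.0), axis=1))
    union = ad.add(union, Tensor(g2.sum(axis=1)))
    degenerate = union.data <= 0
    if np.any(degenerate):
        warnings.warn("all-background ground truth with all-zero prediction; "
                      "IoU loss set to 0 for the affected image(s)")
        # add 1 to both numerator and denominator of the degenerate ratios so
        # each evaluates to exactly 1 (loss contribution 0), gradient-free
        fix = degenerate.astype(float)
        inter = ad.add(inter, Tensor(fix))
        union = ad.add(union, Tensor(fix))
    per_image = ad.add(ad.mul(ad.mul(inter, ad.power(union, -1.0)), -1.0), 1.0)
    if reduction == "sum":
        return ad.tsum(per_image)
    if reduction == "mean":
        return ad.tmean(per_image)
    raise ValueError(f"unknown reduction {reduction!r}")


def total_loss(pred, gt, reduction: str = "sum") -> LossValue:
    """BCE + IoU; `graph` carries the differentiable scalar for training."""
    b = bce_loss(pred, gt, reduction=reduction)
    i = iou_loss(pred, gt, reduction=reduction)
    t = ad.add(b, i)
    return LossValue(bce=b.item(), iou=i.item(), total=b.item() + i.item(), graph=t)
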