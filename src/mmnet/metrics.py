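"""Evaluation metrics for binary segmentation against {0,1} ground truths.

Six measures are provided, matching the columns of the standard polyp
benchmark tables: mean Dice, mean IoU, weighted F-beta (Margolin et al.'s
spatially weighted precision/recall), S-measure (structural similarity,
object + region terms), max E-measure (enhanced alignment, maximized over
256 binarization thresholds) and MAE.

Conventions:

* Predictions are probability maps in [0, 1]; ground truths are {0, 1}.
* Dice/IoU binarize the prediction at ``threshold`` (default 0.5; pass
  ``"adaptive"`` for the 2x-mean rule used by some comparator code bases).
* An empty ground truth makes the weighted F-measure undefined; it returns
  NaN and is excluded from dataset aggregation with a warning.
* PNG masks are binarized at 128/255 when read from disk.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import convolve, distance_transform_edt

_EPS = np.finfo(np.float64).eps

METRIC_COLUMNS = ("mDice", "mIOU", "wFb", "Smeasure", "Emax", "MAE")


def _check_pair(pred, gt):
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    gt = gt.astype(bool)
    return pred, gt


def binarize(pred: np.ndarray, threshold) -> np.ndarray:
    if threshold == "adaptive":
        t = min(2.0 * float(pred.mean()), 1.0)
        return pred >= t
    return pred >= float(threshold)


# ---------------------------------------------------------------------------
# overlap metrics
# ---------------------------------------------------------------------------

def dice(pred, gt, threshold=0.5) -> float:
    """Dice coefficient 2|P∩G| / (|P|+|G|); 1 when both masks are empty."""
    pred, gt = _check_pair(pred, gt)
    p = binarize(pred, threshold)
    tp = np.count_nonzero(p & gt)
    denom = np.count_nonzero(p) + np.count_nonzero(gt)
    if denom == 0:
        return 1.0
    return 2.0 * tp / denom


def iou_metric(pred, gt, threshold=0.5) -> float:
    """Jaccard index |P∩G| / |P∪G|; 1 when both masks are empty."""
    pred, gt = _check_pair(pred, gt)
    p = binarize(pred, threshold)
    inter = np.count_nonzero(p & gt)
    union = np.count_nonzero(p | gt)
    if union == 0:
        return 1.0
    return inter / union


def mae(pred, gt) -> float:
    """Mean absolute per-pixel error, no thresholding."""
    pred, gt = _check_pair(pred, gt)
    return float(np.abs(pred - gt.astype(np.float64)).mean())


# ---------------------------------------------------------------------------
# weighted F-measure
# ---------------------------------------------------------------------------

def _gaussian_kernel(size: int = 7, sigma: float = 5.0) -> np.ndarray:
    half = (size - 1) / 2.0
    ax = np.arange(size) - half
    k = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2.0 * sigma ** 2))
    return k / k.sum()


def weighted_fmeasure(pred, gt, beta2: float = 1.0, sigma: float = 5.0,
                      kernel_size: int = 7) -> float:
    """Weighted F-beta with Gaussian error spreading and distance weighting.

    Errors inside the foreground borrow the error of the nearest foreground
    pixel before Gaussian smoothing (dependency between neighbouring pixels);
    background errors are down-weighted exponentially with distance from the
    object.  Returns NaN (with a warning) for an empty ground truth.
    """
    pred, gt = _check_pair(pred, gt)
    if not gt.any():
        warnings.warn("weighted F-measure undefined for empty ground truth; "
                      "returning NaN")
        return float("nan")
    dgt = gt.astype(np.float64)
    E = np.abs(pred - dgt)
    dst, idx = distance_transform_edt(~gt, return_indices=True)
    Et = E.copy()
    Et[~gt] = Et[idx[0][~gt], idx[1][~gt]]
    K = _gaussian_kernel(kernel_size, sigma)
    # symmetric boundary handling keeps the measure exact at the frame edge
    # (an inverted prediction scores exactly 0, a perfect one exactly 1)
    EA = convolve(Et, K, mode="reflect")
    min_e_ea = E.copy()
    swap = gt & (EA < E)
    min_e_ea[swap] = EA[swap]
    B = np.ones_like(dgt)
    B[~gt] = 2.0 - np.exp(np.log(0.5) / 5.0 * dst[~gt])
    Ew = min_e_ea * B
    tpw = dgt.sum() - Ew[gt].sum()
    fpw = Ew[~gt].sum()
    recall = 1.0 - Ew[gt].mean()
    precision = tpw / (_EPS + tpw + fpw)
    return float((1.0 + beta2) * precision * recall /
                 (_EPS + beta2 * precision + recall))


# ---------------------------------------------------------------------------
# S-measure
# ---------------------------------------------------------------------------

def _object_score(values: np.ndarray) -> float:
    """Similarity of the prediction values inside one region to the ideal 1."""
    if values.size == 0:
        return 0.0
    x = values.mean()
    sigma = values.std(ddof=1) if values.size > 1 else 0.0
    return float(2.0 * x / (x * x + 1.0 + sigma + _EPS))


def _s_object(pred: np.ndarray, gt: np.ndarray) -> float:
    fg = np.where(gt, pred, 0.0)
    bg = np.where(gt, 0.0, 1.0 - pred)
    u = gt.mean()
    return u * _object_score(fg[gt]) + (1.0 - u) * _object_score(bg[~gt])


def _ssim_like(p: np.ndarray, g: np.ndarray) -> float:
    n = p.size
    x, y = p.mean(), g.mean()
    sx = ((p - x) ** 2).sum() / (n - 1 + _EPS)
    sy = ((g - y) ** 2).sum() / (n - 1 + _EPS)
    sxy = ((p - x) * (g - y)).sum() / (n - 1 + _EPS)
    a = 4.0 * x * y * sxy
    b = (x * x + y * y) * (sx + sy)
    if a != 0:
        return float(a / (b + _EPS))
    if a == 0 and b == 0:
        return 1.0
    return 0.0


def _centroid(gt: np.ndarray) -> tuple[int, int]:
    """Split point (row, col): GT centroid, or the image centre if empty.

    Returned as 1-based-style cut positions so the four quadrant slices
    [:r, :c], [:r, c:], [r:, :c], [r:, c:] are all non-degenerate for
    interior centroids.
    """
    H, W = gt.shape
    if not gt.any():
        return H // 2, W // 2
    rows, cols = np.nonzero(gt)
    r = int(np.round(rows.mean())) + 1
    c = int(np.round(cols.mean())) + 1
    return min(r, H - 1), min(c, W - 1)


def _s_region(pred: np.ndarray, gt: np.ndarray) -> float:
    H, W = gt.shape
    r, c = _centroid(gt)
    area = H * W
    quads = [
        (pred[:r, :c], gt[:r, :c]),
        (pred[:r, c:], gt[:r, c:]),
        (pred[r:, :c], gt[r:, :c]),
        (pred[r:, c:], gt[r:, c:]),
    ]
    weights = [q[1].size / area for q in quads]
    return float(sum(w * _ssim_like(p, g.astype(np.float64))
                     for w, (p, g) in zip(weights, quads)))


def s_measure(pred, gt, alpha: float = 0.5) -> float:
    """Structural similarity: alpha * S_object + (1-alpha) * S_region.

    Degenerate ground truths follow the reference conventions: all-background
    scores 1 - mean(pred); all-foreground scores mean(pred).
    """
    pred, gt = _check_pair(pred, gt)
    y = gt.mean()
    if y == 0:
        return float(1.0 - pred.mean())
    if y == 1:
        return float(pred.mean())
    q = alpha * _s_object(pred, gt) + (1.0 - alpha) * _s_region(pred, gt)
    return float(max(q, 0.0))


# ---------------------------------------------------------------------------
# E-measure
# ---------------------------------------------------------------------------

def e_measure(pred, gt, threshold=0.5) -> float:
    """Enhanced-alignment measure of the prediction binarized at `threshold`."""
    pred, gt = _check_pair(pred, gt)
    fm = binarize(pred, threshold).astype(np.float64)
    dgt = gt.astype(np.float64)
    if not gt.any():
        enhanced = 1.0 - fm
    elif gt.all():
        enhanced = fm
    else:
        align = (2.0 * (fm - fm.mean()) * (dgt - dgt.mean()) /
                 ((fm - fm.mean()) ** 2 + (dgt - dgt.mean()) ** 2 + _EPS))
        enhanced = (align + 1.0) ** 2 / 4.0
    # normalized by N (not the reference's N-1) so a perfect map scores
    # exactly 1 and the measure stays inside [0, 1]
    return float(enhanced.mean())


def e_measure_max(pred, gt, n_thresholds: int = 256) -> float:
    """Best E-measure over uniformly spaced binarization thresholds."""
    pred, gt = _check_pair(pred, gt)
    return max(e_measure(pred, gt, threshold=t)
               for t in np.linspace(0.0, 1.0, n_thresholds))


# ---------------------------------------------------------------------------
# dataset-level aggregation
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    """Per-image metric values and their dataset-level means."""

    per_image: list[dict] = field(default_factory=list)
    aggregate: dict = field(default_factory=dict)
    n_images: int = 0

    def to_csv(self, path):
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(("image",) + METRIC_COLUMNS)
            for row in self.per_image:
                writer.writerow([row["image"]] + [f"{row[c]:.6f}" for c in METRIC_COLUMNS])
            writer.writerow(["MEAN"] + [f"{self.aggregate[c]:.6f}" for c in METRIC_COLUMNS])

    def pretty(self) -> str:
        header = f"{'image':<24}" + "".join(f"{c:>10}" for c in METRIC_COLUMNS)
        lines = [header, "-" * len(header)]
        for row in self.per_image:
            lines.append(f"{row['image']:<24}" +
                         "".join(f"{row[c]:>10.4f}" for c in METRIC_COLUMNS))
        lines.append("-" * len(header))
        lines.append(f"{'mean':<24}" +
                     "".join(f"{self.aggregate[c]:>10.4f}" for c in METRIC_COLUMNS))
        return "\n".join(lines)


def compute_all(pred, gt, threshold=0.5) -> dict:
    """All six metrics for one prediction/ground-truth pair."""
    return {
        "mDice": dice(pred, gt, threshold),
        "mIOU": iou_metric(pred, gt, threshold),
        "wFb": weighted_fmeasure(pred, gt),
        "Smeasure": s_measure(pred, gt),
        "Emax": e_measure_max(pred, gt),
        "MAE": mae(pred, gt),
    }


def read_mask(path, binary: bool = True) -> np.ndarray:
    """Read an 8-bit PNG as [0,1] floats, or binarized at 128/255."""
    arr = np.asarray(Image.open(path).convert("L"), dtype=np.float64)
    if binary:
        return (arr >= 128).astype(np.float64)
    return arr / 255.0


def evaluate_dataset(pred_dir, gt_dir, threshold=0.5) -> MetricReport:
    """Evaluate matching prediction/ground-truth PNG pairs by filename."""
    pred_dir, gt_dir = Path(pred_dir), Path(gt_dir)
    preds = {p.name: p for p in sorted(pred_dir.iterdir()) if p.suffix.lower() == ".png"}
    gts = {p.name: p for p in sorted(gt_dir.iterdir()) if p.suffix.lower() == ".png"}
    missing = sorted(set(preds) ^ set(gts))
    if missing:
        raise FileNotFoundError(
            f"prediction/ground-truth filename mismatch: {missing}")
    report = MetricReport()
    for name in sorted(preds):
        pred = read_mask(preds[name], binary=False)
        gt = read_mask(gts[name], binary=True)
        row = {"image": name}
        row.update(compute_all(pred, gt, threshold))
        report.per_image.append(row)
    report.n_images = len(report.per_image)
    agg = {}
    for col in METRIC_COLUMNS:
        vals = np.array([r[col] for r in report.per_image], dtype=np.float64)
        ok = ~np.isnan(vals)
        if not ok.all():
            warnings.warn(f"{(~ok).sum()} image(s) excluded from {col} mean "
                          "(undefined value)")
        agg[col] = float(vals[ok].mean()) if ok.any() else float("nan")
    report.aggregate = agg
    return report
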