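"""Metric correctness against brute-force loop oracles on small maps.

The oracles below re-derive each measure from its definition with explicit
Python loops (nearest-foreground search, hand-built Gaussian kernel,
per-quadrant statistics), independent of the vectorized implementations.
"""

import numpy as np
import pytest
from PIL import Image

from mmnet import metrics as M

RNG = np.random.default_rng(7)


def random_pair(rng, shape=(16, 16), ensure_fg=True):
    pred = rng.random(shape)
    gt = rng.random(shape) > 0.5
    if ensure_fg and not gt.any():
        gt[0, 0] = True
    if ensure_fg and gt.all():
        gt[0, 0] = False
    return pred, gt


# ---------------------------------------------------------------------------
# loop oracles
# ---------------------------------------------------------------------------

def dice_oracle(pred, gt, thr=0.5):
    tp = fp = fn = 0
    for p, g in zip(pred.ravel(), gt.ravel()):
        pb = p >= thr
        tp += pb and g
        fp += pb and not g
        fn += (not pb) and g
    return 2 * tp / (2 * tp + fp + fn) if (tp + fp + fn) else 1.0


def iou_oracle(pred, gt, thr=0.5):
    inter = union = 0
    for p, g in zip(pred.ravel(), gt.ravel()):
        pb = p >= thr
        inter += pb and g
        union += pb or g
    return inter / union if union else 1.0


def mae_oracle(pred, gt):
    return sum(abs(p - float(g)) for p, g in zip(pred.ravel(), gt.ravel())) / pred.size


def _reflect(i, n):
    """Half-sample symmetric boundary index (d c b a | a b c d | d c b a)."""
    period = 2 * n
    i = i % period
    if i < 0:
        i += period
    return i if i < n else period - 1 - i


def wfb_oracle(pred, gt):
    """Loop re-derivation of the weighted F-measure (beta^2 = 1).

    Nearest-foreground ties are broken by smallest column then row, the
    convention of the exact Euclidean feature transform used by the
    implementation.
    """
    H, W = gt.shape
    fg = [(i, j) for i in range(H) for j in range(W) if gt[i, j]]
    E = np.abs(pred - gt.astype(float))
    Et = E.copy()
    dst = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            if not gt[i, j]:
                d2, nj, ni = min(((i - a) ** 2 + (j - b) ** 2, b, a) for a, b in fg)
                dst[i, j] = np.sqrt(d2)
                Et[i, j] = E[ni, nj]
    K = np.zeros((7, 7))
    for u in range(7):
        for v in range(7):
            K[u, v] = np.exp(-((u - 3) ** 2 + (v - 3) ** 2) / (2 * 5.0 ** 2))
    K /= K.sum()
    EA = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            acc = 0.0
            for u in range(7):
                for v in range(7):
                    a, b = _reflect(i + u - 3, H), _reflect(j + v - 3, W)
                    acc += Et[a, b] * K[u, v]
            EA[i, j] = acc
    mea = np.where(gt & (EA < E), EA, E)
    B = np.where(gt, 1.0, 2.0 - np.exp(np.log(0.5) / 5.0 * dst))
    Ew = mea * B
    eps = np.finfo(float).eps
    tpw = gt.sum() - Ew[gt].sum()
    fpw = Ew[~gt].sum()
    R = 1 - Ew[gt].mean()
    P = tpw / (eps + tpw + fpw)
    return 2 * P * R / (eps + P + R)


def _ssim_oracle(p, g):
    n = p.size
    eps = np.finfo(float).eps
    x, y = p.mean(), g.mean()
    sx = sum((v - x) ** 2 for v in p.ravel()) / (n - 1 + eps)
    sy = sum((v - y) ** 2 for v in g.ravel()) / (n - 1 + eps)
    sxy = sum((a - x) * (b - y) for a, b in zip(p.ravel(), g.ravel())) / (n - 1 + eps)
    alpha = 4 * x * y * sxy
    beta = (x * x + y * y) * (sx + sy)
    if alpha != 0:
        return alpha / (beta + eps)
    return 1.0 if beta == 0 else 0.0


def smeasure_oracle(pred, gt, alpha=0.5):
    eps = np.finfo(float).eps
    y = gt.mean()
    if y == 0:
        return 1 - pred.mean()
    if y == 1:
        return pred.mean()
    # object term
    def obj(vals):
        if vals.size == 0:
            return 0.0
        x = vals.mean()
        s = vals.std(ddof=1) if vals.size > 1 else 0.0
        return 2 * x / (x * x + 1 + s + eps)
    u = gt.mean()
    so = u * obj(pred[gt]) + (1 - u) * obj((1 - pred)[~gt])
    # region term
    H, W = gt.shape
    rows, cols = np.nonzero(gt)
    r = min(int(np.round(rows.mean())) + 1, H - 1)
    c = min(int(np.round(cols.mean())) + 1, W - 1)
    sr = 0.0
    for ps, gs in [(pred[:r, :c], gt[:r, :c]), (pred[:r, c:], gt[:r, c:]),
                   (pred[r:, :c], gt[r:, :c]), (pred[r:, c:], gt[r:, c:])]:
        sr += (gs.size / (H * W)) * _ssim_oracle(ps, gs.astype(float))
    return max(alpha * so + (1 - alpha) * sr, 0.0)


def emeasure_oracle(pred, gt, thr):
    eps = np.finfo(float).eps
    fm = (pred >= thr).astype(float)
    g = gt.astype(float)
    if not gt.any():
        enh = 1 - fm
    elif gt.all():
        enh = fm
    else:
        af, ag = fm - fm.mean(), g - g.mean()
        align = 2 * af * ag / (af ** 2 + ag ** 2 + eps)
        enh = (align + 1) ** 2 / 4
    return enh.mean()


def emax_oracle(pred, gt, n_thr=256):
    return max(emeasure_oracle(pred, gt, t) for t in np.linspace(0, 1, n_thr))


# ---------------------------------------------------------------------------
# oracle-equivalence tests
# ---------------------------------------------------------------------------

def test_simple_metrics_match_loop_oracles():
    for _ in range(30):
        pred, gt = random_pair(RNG)
        assert M.dice(pred, gt) == pytest.approx(dice_oracle(pred, gt), abs=1e-6)
        assert M.iou_metric(pred, gt) == pytest.approx(iou_oracle(pred, gt), abs=1e-6)
        assert M.mae(pred, gt) == pytest.approx(mae_oracle(pred, gt), abs=1e-6)


def test_structure_metrics_match_loop_oracles():
    for _ in range(8):
        pred, gt = random_pair(RNG)
        assert M.weighted_fmeasure(pred, gt) == pytest.approx(
            wfb_oracle(pred, gt), abs=1e-6)
        assert M.s_measure(pred, gt) == pytest.approx(
            smeasure_oracle(pred, gt), abs=1e-6)
        assert M.e_measure_max(pred, gt) == pytest.approx(
            emax_oracle(pred, gt), abs=1e-6)


def test_counting_example_partial_overlap():
    # pred: top-left 2x2 block (4 px); gt: first two rows (8 px)
    pred = np.zeros((4, 4))
    pred[:2, :2] = 1.0
    gt = np.zeros((4, 4), dtype=bool)
    gt[:2] = True
    assert M.dice(pred, gt) == pytest.approx(2 * 4 / (4 + 8))
    assert M.iou_metric(pred, gt) == pytest.approx(4 / 8)


def test_dice_iou_functional_identity():
    for _ in range(100):
        pred, gt = random_pair(RNG, (12, 12))
        d, i = M.dice(pred, gt), M.iou_metric(pred, gt)
        assert d == pytest.approx(2 * i / (1 + i), abs=1e-12)


def test_perfect_prediction_is_optimal_everywhere():
    for _ in range(50):
        _, gt = random_pair(RNG, (12, 12))
        perfect = gt.astype(float)
        assert M.dice(perfect, gt) == 1.0
        assert M.iou_metric(perfect, gt) == 1.0
        assert M.weighted_fmeasure(perfect, gt) == pytest.approx(1.0, abs=1e-9)
        assert M.s_measure(perfect, gt) == pytest.approx(1.0, abs=1e-6)
        assert M.e_measure_max(perfect, gt) == pytest.approx(1.0, abs=1e-9)
        assert M.mae(perfect, gt) == 0.0
        # and no other random prediction does better
        rival = RNG.random(gt.shape)
        assert M.dice(rival, gt) <= 1.0 and M.mae(rival, gt) >= 0.0


def test_complement_prediction_scores_worst():
    pred, gt = random_pair(RNG)
    comp = 1.0 - gt.astype(float)
    assert M.dice(comp, gt) == 0.0
    assert M.mae(comp, gt) == 1.0
    assert M.weighted_fmeasure(comp, gt) == pytest.approx(0.0, abs=1e-9)


def test_all_metrics_bounded_unit_interval():
    for _ in range(200):
        pred, gt = random_pair(RNG, (8, 8))
        vals = M.compute_all(pred, gt)
        for name, v in vals.items():
            assert 0.0 <= v <= 1.0, (name, v)


def test_smeasure_improves_as_prediction_blends_toward_truth():
    for _ in range(20):
        pred, gt = random_pair(RNG)
        far = M.s_measure(pred, gt)
        near = M.s_measure(0.2 * pred + 0.8 * gt, gt)
        assert near >= far - 1e-9


def test_emax_upper_bounds_fixed_threshold_score():
    pred, gt = random_pair(RNG)
    assert M.e_measure_max(pred, gt) >= M.e_measure(pred, gt, 0.5) - 1e-12


def test_emeasure_constant_half_prediction_agrees_with_oracle():
    gt = np.zeros((8, 8), dtype=bool)
    gt[:4] = True
    pred = np.full((8, 8), 0.5)
    for t in (0.25, 0.5, 0.75):
        assert M.e_measure(pred, gt, t) == pytest.approx(
            emeasure_oracle(pred, gt, t), abs=1e-6)


def test_empty_gt_wfb_flagged_and_excluded(tmp_path):
    with pytest.warns(UserWarning, match="undefined"):
        assert np.isnan(M.weighted_fmeasure(RNG.random((8, 8)), np.zeros((8, 8))))


def test_degenerate_gt_smeasure_conventions():
    pred = np.full((6, 6), 0.3)
    assert M.s_measure(pred, np.zeros((6, 6))) == pytest.approx(0.7)
    assert M.s_measure(pred, np.ones((6, 6))) == pytest.approx(0.3)


def test_adaptive_threshold_mode_runs():
    pred, gt = random_pair(RNG)
    assert 0.0 <= M.dice(pred, gt, threshold="adaptive") <= 1.0


def test_evaluate_dataset_on_gt_copies_is_perfect(tmp_path):
    gt_dir = tmp_path / "gt"
    pred_dir = tmp_path / "pred"
    gt_dir.mkdir()
    pred_dir.mkdir()
    rng = np.random.default_rng(3)
    for i in range(3):
        gt = (rng.random((24, 24)) > 0.6).astype(np.uint8) * 255
        gt[0, 0] = 255  # keep nonempty
        for d in (gt_dir, pred_dir):
            Image.fromarray(gt).save(d / f"img{i}.png")
    report = M.evaluate_dataset(pred_dir, gt_dir)
    assert report.n_images == 3
    for col in ("mDice", "mIOU", "wFb", "Smeasure", "Emax"):
        assert report.aggregate[col] == pytest.approx(1.0, abs=1e-6)
    assert report.aggregate["MAE"] == pytest.approx(0.0, abs=1e-9)
    # aggregate is the arithmetic mean of per-image values
    for col in M.METRIC_COLUMNS:
        assert report.aggregate[col] == pytest.approx(
            np.mean([r[col] for r in report.per_image]))
    # CSV round trip and pretty table carry the benchmark column order
    report.to_csv(tmp_path / "out.csv")
    header = (tmp_path / "out.csv").read_text().splitlines()[0]
    assert header == "image,mDice,mIOU,wFb,Smeasure,Emax,MAE"
    assert "mDice" in report.pretty()


def test_evaluate_dataset_mismatched_files_abort(tmp_path):
    (tmp_path / "gt").mkdir()
    (tmp_path / "pred").mkdir()
    Image.fromarray(np.zeros((4, 4), dtype=np.uint8)).save(tmp_path / "gt" / "a.png")
    with pytest.raises(FileNotFoundError, match="mismatch"):
        M.evaluate_dataset(tmp_path / "pred", tmp_path / "gt")
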