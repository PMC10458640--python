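"""Training loop, augmentation, multiscale batching, checkpoints, inference.

The recipe follows the published setup: Adam at 1e-4 with polynomial decay
(power 0.9 by default, or a step x0.1 alternative), 60 epochs, batch 16,
inputs rescaled to 352x352, multiscale factors {0.75, 1, 1.25} resampled per
batch, and probabilistic rotation (up to 90 degrees) plus horizontal and
vertical flips applied identically to image and mask.  Everything is driven
by one integer seed: weight init, shuffling, augmentation draws and the
multiscale schedule, so two runs with the same seed produce identical loss
curves.

Images are normalized with ImageNet statistics, matching the pretraining of
the transformer backbone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .config import TrainConfig, ModelConfig, save_yaml, load_yaml, _to_plain, _dict_to_dataclass
from .losses import total_loss
from .metrics import dice
from .model import MMNet, build_model

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])

IMAGE_EXTS = (".png", ".jpg", ".jpeg")


# ---------------------------------------------------------------------------
# data loading
# ---------------------------------------------------------------------------

def list_pairs(data_dir) -> list[tuple[Path, Path]]:
    """Match images/ and masks/ by stem in the Kvasir-SEG layout."""
    data_dir = Path(data_dir)
    img_dir, mask_dir = data_dir / "images", data_dir / "masks"
    if not img_dir.is_dir() or not mask_dir.is_dir():
        raise FileNotFoundError(f"{data_dir} must contain images/ and masks/")
    masks = {p.stem: p for p in mask_dir.iterdir() if p.suffix.lower() in IMAGE_EXTS}
    pairs = []
    unmatched = []
    for img in sorted(img_dir.iterdir()):
        if img.suffix.lower() not in IMAGE_EXTS:
            continue
        if img.stem in masks:
            pairs.append((img, masks[img.stem]))
        else:
            unmatched.append(img.name)
    if unmatched:
        raise FileNotFoundError(f"images without masks: {unmatched}")
    if not pairs:
        raise FileNotFoundError(f"no image/mask pairs found under {data_dir}")
    return pairs


def load_pair(img_path, mask_path, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Returns (H x W x 3 float image in [0,1], H x W binary mask)."""
    img = Image.open(img_path).convert("RGB").resize((size, size), Image.BILINEAR)
    mask = Image.open(mask_path).convert("L").resize((size, size), Image.NEAREST)
    return (np.asarray(img, dtype=np.float64) / 255.0,
            (np.asarray(mask, dtype=np.float64) >= 128).astype(np.float64))


def normalize_batch(images: np.ndarray) -> np.ndarray:
    """N x H x W x 3 in [0,1] -> N x 3 x H x W, ImageNet-normalized."""
    x = (images - IMAGENET_MEAN) / IMAGENET_STD
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


# ---------------------------------------------------------------------------
# augmentation and multiscale
# ---------------------------------------------------------------------------

def augment(image: np.ndarray, mask: np.ndarray, rng: np.random.Generator,
            rotate_max_deg: float = 90.0):
    """Shared geometric transform for one image/mask pair.

    Draws: rotation (p=0.5, angle uniform in [-max, max], bilinear for the
    image, nearest for the mask), horizontal flip (p=0.5), vertical flip
    (p=0.5).  The mask stays strictly binary.
    """
    if rng.random() < 0.5:
        angle = rng.uniform(-rotate_max_deg, rotate_max_deg)
        image = ndimage.rotate(image, angle, axes=(0, 1), reshape=False,
                               order=1, mode="reflect")
        mask = ndimage.rotate(mask, angle, axes=(0, 1), reshape=False,
                              order=0, mode="constant")
    if rng.random() < 0.5:
        image, mask = image[:, ::-1], mask[:, ::-1]
    if rng.random() < 0.5:
        image, mask = image[::-1], mask[::-1]
    return np.ascontiguousarray(np.clip(image, 0, 1)), \
        np.ascontiguousarray((mask >= 0.5).astype(np.float64))


def snap32(size: int) -> int:
    """Round up to the next multiple of 32 (backbone stride contract)."""
    return int(-(-size // 32) * 32)


def multiscale_batch(images: np.ndarray, masks: np.ndarray, factor: float,
                     base_size: int):
    """Rescale a normalized NCHW batch and its masks to round(base*factor),
    snapped up to a multiple of 32; bilinear for images, nearest for masks."""
    target = snap32(int(round(base_size * factor)))
    if target == images.shape[-1]:
        return images, masks
    with ad.no_grad():
        imgs = ad.resize_bilinear(Tensor(images), (target, target)).data
    out_masks = ad.resize_nearest(masks, (target, target))
    return imgs, out_masks


def lr_at(epoch: int, cfg: TrainConfig, total_epochs: int | None = None) -> float:
    """Learning rate for a (0-based) epoch under the configured decay."""
    E = total_epochs if total_epochs is not None else cfg.epochs
    e = min(epoch, E - 1)
    if cfg.lr_decay_kind == "poly":
        return cfg.base_lr * (1.0 - e / E) ** cfg.lr_poly_power
    if cfg.lr_decay_kind == "step":
        return cfg.base_lr * cfg.lr_step_factor ** (e // max(E // 3, 1))
    raise ValueError(f"unknown lr_decay_kind {cfg.lr_decay_kind!r}")


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

@dataclass
class Checkpoint:
    state: dict[str, np.ndarray]
    model_config: ModelConfig
    epoch: int = 0
    rng_state: dict | None = None

    def save(self, path):
        meta = {"epoch": self.epoch,
                "model_config": _to_plain(self.model_config),
                "rng_state": self.rng_state}
        arrays = {f"param/{k}": v for k, v in self.state.items()}
        np.savez(path, __meta__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "Checkpoint":
        blob = np.load(path, allow_pickle=False)
        meta = json.loads(str(blob["__meta__"]))
        state = {k[len("param/"):]: blob[k] for k in blob.files if k.startswith("param/")}
        model_cfg = _dict_to_dataclass(ModelConfig, meta["model_config"])
        return cls(state=state, model_config=model_cfg, epoch=meta["epoch"],
                   rng_state=meta.get("rng_state"))

    def build(self) -> MMNet:
        model = build_model(self.model_config, seed=0)
        model.load_state_dict(self.state)
        return model


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    checkpoint: Checkpoint
    history: list[dict] = field(default_factory=list)
    best_val_dice: float = float("nan")
    final_train_dice: float = float("nan")


def _train_dice(model: MMNet, images: np.ndarray, masks: np.ndarray) -> float:
    with ad.no_grad():
        model.eval()
        preds = model(images).data[:, 0]
        model.train()
    return float(np.mean([dice(p, m) for p, m in zip(preds, masks)]))


def train(cfg: TrainConfig, train_dir, val_dir=None, log_path=None) -> TrainResult:
    """Train from a Kvasir-layout directory; returns the best checkpoint.

    The best checkpoint is selected by validation mean Dice when ``val_dir``
    is given, otherwise the final weights are kept.  A JSON-lines log records
    every optimizer step.
    """
    rng = np.random.default_rng([cfg.seed, 0xA])
    pairs = list_pairs(train_dir)
    size = cfg.model.image_size
    images = np.stack([load_pair(i, m, size)[0] for i, m in pairs])
    masks = np.stack([load_pair(i, m, size)[1] for i, m in pairs])

    model = build_model(cfg.model, seed=cfg.seed)
    optimizer = nn.Adam(model.parameters(), lr=cfg.base_lr)

    val_images = val_masks = None
    if val_dir is not None:
        vpairs = list_pairs(val_dir)
        val_images = np.stack([load_pair(i, m, size)[0] for i, m in vpairs])
        val_masks = np.stack([load_pair(i, m, size)[1] for i, m in vpairs])

    log_fh = open(log_path, "w") if log_path else None
    history: list[dict] = []
    best_val = -np.inf
    best_state = None
    n = len(pairs)
    steps_per_epoch = -(-n // cfg.batch_size)
    if cfg.max_iters is not None:
        total_epochs = -(-cfg.max_iters // steps_per_epoch)
    else:
        total_epochs = cfg.epochs
    step = 0
    stop = False
    for epoch in range(total_epochs):
        optimizer.lr = lr_at(epoch, cfg, total_epochs)
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch_imgs, batch_masks = [], []
            for i in idx:
                img, msk = images[i], masks[i]
                if cfg.augment:
                    img, msk = augment(img, msk, rng, cfg.rotate_max_deg)
                batch_imgs.append(img)
                batch_masks.append(msk)
            x = normalize_batch(np.stack(batch_imgs))
            y = np.stack(batch_masks)
            factor = cfg.multiscale_factors[rng.integers(len(cfg.multiscale_factors))]
            x, y = multiscale_batch(x, y, factor, size)
            pred = model(x)
            loss = total_loss(pred, y[:, None], reduction=cfg.loss_reduction)
            if not np.isfinite(loss.total):
                raise FloatingPointError(f"non-finite loss at step {step}")
            optimizer.zero_grad()
            loss.graph.backward()
            optimizer.step()
            step += 1
            record = {"epoch": epoch, "step": step, "loss": loss.total,
                      "bce": loss.bce, "iou": loss.iou, "lr": optimizer.lr}
            history.append(record)
            if log_fh:
                log_fh.write(json.dumps(record) + "\n")
            if cfg.max_iters is not None and step >= cfg.max_iters:
                stop = True
                break
        if val_images is not None:
            vd = _train_dice(model, normalize_batch(val_images), val_masks)
            history.append({"epoch": epoch, "val_dice": vd})
            if log_fh:
                log_fh.write(json.dumps(history[-1]) + "\n")
            if vd > best_val:
                best_val = vd
                best_state = model.state_dict()
        if stop:
            break
    if log_fh:
        log_fh.close()
    final_dice = _train_dice(model, normalize_batch(images), masks)
    state = best_state if best_state is not None else model.state_dict()
    ckpt = Checkpoint(state=state, model_config=cfg.model, epoch=epoch,
                      rng_state=rng.bit_generator.state)
    return TrainResult(checkpoint=ckpt, history=history,
                       best_val_dice=float(best_val) if best_state else float("nan"),
                       final_train_dice=final_dice)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def predict(checkpoint: Checkpoint | str, image_dir, out_dir,
            threshold: float = 0.5) -> list[Path]:
    """Write per-image probability maps and binarized masks as PNGs.

    Outputs are restored to each input's original resolution and mirror the
    input filenames (probability map as <stem>.png in prob/, binary mask in
    masks/).
    """
    if not isinstance(checkpoint, Checkpoint):
        checkpoint = Checkpoint.load(checkpoint)
    model = checkpoint.build().eval()
    size = checkpoint.model_config.image_size
    image_dir, out_dir = Path(image_dir), Path(out_dir)
    prob_dir = out_dir / "prob"
    mask_dir = out_dir / "masks"
    prob_dir.mkdir(parents=True, exist_ok=True)
    mask_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for img_path in sorted(image_dir.iterdir()):
        if img_path.suffix.lower() not in IMAGE_EXTS:
            continue
        orig = Image.open(img_path).convert("RGB")
        w0, h0 = orig.size
        arr = np.asarray(orig.resize((size, size), Image.BILINEAR),
                         dtype=np.float64) / 255.0
        x = normalize_batch(arr[None])
        with ad.no_grad():
            prob = model(x)
            prob = ad.resize_bilinear(prob, (h0, w0)).data[0, 0]
        name = img_path.stem + ".png"
        Image.fromarray((prob * 255).astype(np.uint8)).save(prob_dir / name)
        Image.fromarray(((prob >= threshold) * 255).astype(np.uint8)).save(
            mask_dir / name)
        written.append(prob_dir / name)
    return written
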