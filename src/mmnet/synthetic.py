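"""Seeded generator of colonoscopy-like image/mask pairs.

Real polyp benchmarks share a recognisable statistical structure: one to a
few roughly elliptical, slightly raised and blurred regions on a textured
pink mucosa background, with low foreground/background contrast, specular
highlights from the endoscope light and strong vignetting at the frame
borders.  Polyp sizes span more than two orders of magnitude — the hardest
test sets are dominated by very small lesions.  The generator emulates
exactly these features so training and evaluation code paths can be
exercised end to end without any dataset download:

* blobs are rotated super-ellipses with a smooth random radial perturbation,
  areas drawn log-uniformly from ``blob_area_fraction`` (spanning tiny
  through large lesions);
* foreground colour is the background texture shifted by a (possibly tiny)
  contrast delta, and the foreground/background transition is Gaussian blurred;
* additive specular disks and a multiplicative vignette complete the image.

Masks remain crisp {0, 255} unions of the rendered blob interiors, and every
sample is a pure function of ``(seed, index)`` — the manifest stores the blob
geometry so masks can be re-rendered bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter


@dataclass(frozen=True)
class SyntheticParams:
    """Dataset-level knobs; ranges are inclusive (lo, hi) pairs."""

    image_size: tuple[int, int] = (352, 352)
    n_blobs: tuple[int, int] = (1, 3)
    blob_area_fraction: tuple[float, float] = (0.002, 0.25)  # log-uniform
    contrast_delta: tuple[float, float] = (0.02, 0.35)
    blur_sigma: tuple[float, float] = (1.0, 4.0)
    specular_count: tuple[int, int] = (0, 6)
    vignette_strength: float = 0.35
    seed: int = 0
    allow_empty: bool = False

    def __post_init__(self):
        lo, hi = self.blob_area_fraction
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("blob_area_fraction must lie in (0, 1)")
        for name in ("n_blobs", "contrast_delta", "blur_sigma", "specular_count"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"empty range for {name}")


@dataclass
class SampleRecord:
    """One generated image/mask pair plus its full provenance."""

    image: np.ndarray  # H x W x 3 uint8
    mask: np.ndarray   # H x W uint8 in {0, 255}
    meta: dict = field(default_factory=dict)


def _render_blob_mask(shape: tuple[int, int], blob: dict) -> np.ndarray:
    """Rasterize one perturbed, rotated super-ellipse from its meta dict."""
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    cy, cx = blob["center"]
    theta = blob["rotation"]
    dy, dx = yy - cy, xx - cx
    u = np.cos(theta) * dx + np.sin(theta) * dy
    v = -np.sin(theta) * dx + np.cos(theta) * dy
    a, b = blob["axes"]
    n = blob["exponent"]
    # smooth radial perturbation: r(phi) = 1 + sum_k amp_k cos(k phi + phase_k)
    phi = np.arctan2(v / b, u / a)
    pert = np.ones_like(phi)
    for k, (amp, phase) in enumerate(zip(blob["pert_amp"], blob["pert_phase"]), start=2):
        pert += amp * np.cos(k * phi + phase)
    rho = (np.abs(u / a) ** n + np.abs(v / b) ** n) ** (1.0 / n)
    return rho <= pert


def _sample_blob(rng: np.random.Generator, params: SyntheticParams) -> dict:
    H, W = params.image_size
    lo, hi = params.blob_area_fraction
    for _ in range(100):
        frac = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        area = frac * H * W
        aspect = rng.uniform(0.55, 1.0)
        a = np.sqrt(area / (np.pi * aspect))
        b = a * aspect
        cy = rng.uniform(0, H)
        cx = rng.uniform(0, W)
        margin = 1.35 * max(a, b)  # head-room for the radial perturbation
        if margin <= cy <= H - margin and margin <= cx <= W - margin:
            break
    else:
        raise RuntimeError(
            f"could not place a blob from area-fraction range ({lo}, {hi}) "
            f"inside a {H}x{W} frame after 100 attempts (blobs too large "
            "for the image)")
    n_harm = int(rng.integers(2, 5))
    return {
        "center": (float(cy), float(cx)),
        "axes": (float(a), float(b)),
        "rotation": float(rng.uniform(0, np.pi)),
        "exponent": float(rng.uniform(1.5, 3.0)),
        "pert_amp": [float(x) for x in rng.uniform(0.0, 0.08, size=n_harm)],
        "pert_phase": [float(x) for x in rng.uniform(0, 2 * np.pi, size=n_harm)],
        "area_fraction": frac,
    }


def render_mask(image_size: tuple[int, int], blobs: list[dict]) -> np.ndarray:
    """Union of blob interiors as a {0, 255} uint8 mask (pure meta function)."""
    mask = np.zeros(image_size, dtype=bool)
    for blob in blobs:
        mask |= _render_blob_mask(image_size, blob)
    return (mask * 255).astype(np.uint8)


def generate_sample(params: SyntheticParams, index: int) -> SampleRecord:
    """Deterministic image/mask pair: a pure function of (params.seed, index)."""
    rng = np.random.default_rng([params.seed, index])
    H, W = params.image_size

    n_blobs = int(rng.integers(params.n_blobs[0], params.n_blobs[1] + 1))
    if n_blobs == 0 and not params.allow_empty:
        n_blobs = 1
    blobs = [_sample_blob(rng, params) for _ in range(n_blobs)]
    mask = render_mask((H, W), blobs)
    fg = mask > 0

    # mucosa-like background: smooth correlated noise around a pink base tone
    base = np.array([0.72, 0.42, 0.38]) + rng.uniform(-0.06, 0.06, size=3)
    texture = gaussian_filter(rng.normal(0.0, 1.0, size=(H, W)), sigma=12.0)
    texture = texture / (np.abs(texture).max() + 1e-9)
    fine = gaussian_filter(rng.normal(0.0, 1.0, size=(H, W)), sigma=2.5)
    fine = fine / (np.abs(fine).max() + 1e-9)
    img = base[None, None, :] + 0.10 * texture[..., None] + 0.03 * fine[..., None]

    # foreground: same texture, shifted by a low contrast delta (soft edge)
    contrast = float(rng.uniform(*params.contrast_delta))
    blur = float(rng.uniform(*params.blur_sigma))
    alpha = gaussian_filter(fg.astype(np.float64), sigma=blur)
    tint = np.array([1.0, 0.75, 0.65])  # polyps trend brighter / slightly yellow
    img = img + contrast * alpha[..., None] * tint[None, None, :]

    # specular highlights: small bright Gaussian disks anywhere in the frame
    n_spec = int(rng.integers(params.specular_count[0], params.specular_count[1] + 1))
    spec = np.zeros((H, W))
    for _ in range(n_spec):
        sy, sx = rng.uniform(0, H), rng.uniform(0, W)
        rad = rng.uniform(1.5, 5.0)
        yy, xx = np.mgrid[0:H, 0:W]
        spec += np.exp(-(((yy - sy) ** 2 + (xx - sx) ** 2) / (2 * rad ** 2)))
    img = img + 0.8 * np.clip(spec, 0, 1)[..., None]

    # multiplicative vignette
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    r2 = ((yy - H / 2) / (H / 2)) ** 2 + ((xx - W / 2) / (W / 2)) ** 2
    img = img * (1.0 - params.vignette_strength * np.clip(r2, 0, 1))[..., None]

    image = (np.clip(img, 0, 1) * 255).astype(np.uint8)
    meta = {
        "seed": params.seed,
        "index": index,
        "blobs": blobs,
        "contrast": contrast,
        "blur": blur,
        "n_specular": n_spec,
    }
    return SampleRecord(image=image, mask=mask, meta=meta)


def generate_dataset(params: SyntheticParams, n: int, out_dir) -> dict:
    """Write n samples in the standard images/ + masks/ layout plus a manifest.

    Re-running with identical params and n reproduces byte-identical PNGs.
    Even indices are tagged "train" and odd indices "val" in the manifest so
    callers get a deterministic split for free.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    mask_dir = out_dir / "masks"
    img_dir.mkdir(parents=True, exist_ok=True)
    mask_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"params": asdict(params), "n": n, "samples": []}
    written: list[Path] = []
    try:
        for i in range(n):
            rec = generate_sample(params, i)
            name = f"{i:04d}.png"
            Image.fromarray(rec.image).save(img_dir / name)
            written.append(img_dir / name)
            Image.fromarray(rec.mask).save(mask_dir / name)
            written.append(mask_dir / name)
            entry = dict(rec.meta)
            entry["file"] = name
            entry["split"] = "train" if i % 2 == 0 else "val"
            manifest["samples"].append(entry)
    except Exception:
        for path in written:  # partial-write cleanup
            path.unlink(missing_ok=True)
        raise
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
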