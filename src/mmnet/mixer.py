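"""Convolutional mixing module and per-channel gating.

The module turns the global feature map into a vector of per-channel weights
in three steps:

1. **Patch embedding** — z0 = LN(GELU(Conv(k=p, stride=p))), after reflect
   padding so the spatial dims divide by the patch size p.
2. **Mixing blocks**, repeated ``depth`` times, each two residual halves:

       z_l    = LN(GELU(DepthwiseConv_k(z_{l-1})) + z_{l-1})   (spatial mixing)
       z_{l+1}= LN(GELU(PointwiseConv_1x1(z_l)) + z_l)         (channel mixing)

   Depthwise convolutions with a large kernel mix information across distant
   spatial positions; the 1x1 convolutions mix across channels — together a
   cheap stand-in for self-attention.  Both halves carry a residual
   connection and layer normalization (never batch norm) over channels.
3. **Channel gate** — global average pool over space, then a sigmoid, giving
   one weight in (0, 1) per channel.  The gate multiplies the global feature
   map channelwise; a small mask head (1x1 conv, bilinear upsample, sigmoid)
   reads the gated map into a probability mask.

With the default hyperparameters (patch 9, kernel 28) the token grid at
stride 8 would be far smaller than the kernel, so by default the global map
is first upsampled to the network input resolution (``operate_resolution =
"input"``: 352 -> pad 360 -> 40x40 tokens); ``"stride8"`` mode patches the
map directly and clamps the kernel to the token-grid size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import nn


@dataclass(frozen=True)
class MixerConfig:
    depth: int = 20
    dim: int = 64
    kernel_size: int = 28
    patch_size: int = 9
    operate_resolution: str = "input"  # "input" | "stride8"

    def __post_init__(self):
        if self.depth < 0 or self.dim < 1 or self.kernel_size < 1 or self.patch_size < 1:
            raise ValueError("invalid mixer hyperparameters")
        if self.operate_resolution not in ("input", "stride8"):
            raise ValueError("operate_resolution must be 'input' or 'stride8'")


def _same_pads(k: int) -> tuple[int, int, int, int]:
    """'Same' padding for stride 1; even kernels pad asymmetrically."""
    lo = (k - 1) // 2
    hi = k // 2
    return (lo, hi, lo, hi)


class PatchEmbed(nn.Module):
    def __init__(self, in_channels: int, dim: int, patch_size: int,
                 use_norm: bool = True, use_act: bool = True):
        super().__init__()
        self.patch_size = patch_size
        self.use_act = use_act
        self.proj = nn.Conv2d(in_channels, dim, patch_size, stride=patch_size)
        self.norm = nn.LayerNorm2d(dim) if use_norm else nn.Identity()

    def forward(self, x):
        p = self.patch_size
        H, W = x.data.shape[-2:]
        pad_h = (-H) % p
        pad_w = (-W) % p
        if pad_h or pad_w:
            x = ad.pad2d(x, (0, pad_h, 0, pad_w), mode="reflect")
        z = self.proj(x)
        if self.use_act:
            z = ad.gelu(z)
        return self.norm(z)


class MixBlock(nn.Module):
    def __init__(self, dim: int, kernel_size: int):
        super().__init__()
        self.dw = nn.Conv2d(dim, dim, kernel_size, padding=_same_pads(kernel_size),
                            groups=dim)
        self.norm1 = nn.LayerNorm2d(dim)
        self.pw = nn.Conv2d(dim, dim, 1)
        self.norm2 = nn.LayerNorm2d(dim)

    def forward(self, z):
        z = self.norm1(ad.add(ad.gelu(self.dw(z)), z))
        z = self.norm2(ad.add(ad.gelu(self.pw(z)), z))
        return z


def channel_gate(z_final) -> "ad.Tensor":
    """Spatial average pool then sigmoid: one weight in (0,1) per channel."""
    return ad.sigmoid(ad.tmean(z_final, axis=(2, 3)))


def apply_gate(g, gate):
    """Multiply the global feature map channelwise by the gate vector."""
    g_t = g if isinstance(g, ad.Tensor) else ad.Tensor(g)
    gate_t = gate if isinstance(gate, ad.Tensor) else ad.Tensor(gate)
    if gate_t.data.shape[-1] != g_t.data.shape[1]:
        raise ValueError(
            f"gate length {gate_t.data.shape[-1]} != map channels {g_t.data.shape[1]}")
    n, c = gate_t.data.shape if gate_t.data.ndim == 2 else (1, gate_t.data.shape[0])
    return ad.mul(g_t, ad.reshape(gate_t, (n, c, 1, 1)))


class MixingModule(nn.Module):
    """Patch embed -> depth x MixBlock -> channel gate."""

    def __init__(self, in_channels: int, cfg: MixerConfig,
                 adapt_channels: bool = False):
        super().__init__()
        self.cfg = cfg
        if cfg.dim != in_channels and not adapt_channels:
            # pooled mixer output must line up with the gated map's channels
            raise ValueError(
                f"mixer dim ({cfg.dim}) must equal the global feature map "
                f"channels ({in_channels}); set them equal in the config or "
                "pass adapt_channels=True")
        if cfg.dim != in_channels:
            self.adapter = nn.Conv2d(in_channels, cfg.dim, 1)
            self.gate_proj = nn.Linear(cfg.dim, in_channels)
        else:
            self.adapter = None
            self.gate_proj = None
        self.patch_embed = PatchEmbed(cfg.dim, cfg.dim, cfg.patch_size)
        self.blocks = [MixBlock(cfg.dim, cfg.kernel_size) for _ in range(cfg.depth)]
        self._built_kernel = cfg.kernel_size

    def forward(self, g, input_hw: tuple[int, int] | None = None):
        """g: global feature map (stride 8). Returns the gate vector (N, C)."""
        x = g
        if self.cfg.operate_resolution == "input":
            if input_hw is None:
                raise ValueError("input_hw required in 'input' resolution mode")
            x = ad.resize_bilinear(x, input_hw)
        if self.adapter is not None:
            x = self.adapter(x)
        z = self.patch_embed(x)
        th, tw = z.data.shape[-2:]
        if self.cfg.operate_resolution == "stride8" and self._built_kernel > min(th, tw):
            raise ValueError(
                f"mixer kernel {self._built_kernel} exceeds the {th}x{tw} token "
                "grid; reduce kernel_size or use operate_resolution='input'")
        for blk in self.blocks:
            z = blk(z)
        pooled = ad.tmean(z, axis=(2, 3))
        if self.gate_proj is not None:
            pooled = self.gate_proj(pooled)
        return ad.sigmoid(pooled)


class MaskHead(nn.Module):
    """1x1 conv to one channel, bilinear upsample, sigmoid.

    The mixing-module description ends at the gated feature map; collapsing
    it to a single-channel probability mask is this package's plumbing.
    """

    def __init__(self, in_channels: int):
        super().__init__()
        self.proj = nn.Conv2d(in_channels, 1, 1)

    def forward(self, gated, out_size: tuple[int, int]):
        logits = self.proj(gated)
        return ad.sigmoid(ad.resize_bilinear(logits, out_size))


def stride8_kernel(cfg: MixerConfig, map_hw: tuple[int, int]) -> int:
    """Kernel clamped to the token grid, for stride8-mode construction."""
    th = int(np.ceil(map_hw[0] / cfg.patch_size))
    tw = int(np.ceil(map_hw[1] / cfg.patch_size))
    return min(cfg.kernel_size, th, tw)
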