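"""Pyramid Vision Transformer v2, b2 capacity, on the NumPy autodiff core.

Four stages of overlapping patch embedding followed by transformer blocks
with spatial-reduction attention (SRA): keys/values are computed from a
sr x sr strided-convolution downsampling of the token grid, which keeps
attention cost linear-ish at high resolution. The feed-forward blocks carry
the v2 depthwise 3x3 convolution between the two linear layers.

b2 configuration: embedding dims (64, 128, 320, 512), depths (3, 4, 6, 3),
heads (1, 2, 5, 8), MLP ratios (8, 8, 4, 4), spatial-reduction ratios
(8, 4, 2, 1).  Weights initialize randomly; ImageNet-pretrained weights can
be supplied as an .npz state dict through the backbone builder.
"""

from __future__ import annotations

import math

import numpy as np

from .. import autodiff as ad
from .. import nn


class OverlapPatchEmbed(nn.Module):
    def __init__(self, in_ch: int, embed_dim: int, patch: int, stride: int):
        super().__init__()
        self.proj = nn.Conv2d(in_ch, embed_dim, patch, stride=stride,
                              padding=patch // 2)
        self.norm = nn.LayerNorm(embed_dim)

    def forward(self, x):
        x = self.proj(x)  # (N, C, H', W')
        n, c, h, w = x.data.shape
        tokens = ad.transpose(ad.reshape(x, (n, c, h * w)), (0, 2, 1))
        return self.norm(tokens), h, w


def _tokens_to_map(tokens, h: int, w: int):
    n, _, c = tokens.data.shape
    return ad.reshape(ad.transpose(tokens, (0, 2, 1)), (n, c, h, w))


class SRAttention(nn.Module):
    def __init__(self, dim: int, heads: int, sr_ratio: int):
        super().__init__()
        self.heads = heads
        self.head_dim = dim // heads
        self.scale = 1.0 / math.sqrt(self.head_dim)
        self.sr_ratio = sr_ratio
        self.q = nn.Linear(dim, dim)
        self.kv = nn.Linear(dim, dim * 2)
        self.proj = nn.Linear(dim, dim)
        if sr_ratio > 1:
            self.sr = nn.Conv2d(dim, dim, sr_ratio, stride=sr_ratio)
            self.norm = nn.LayerNorm(dim)

    def forward(self, x, h: int, w: int):
        n, N, c = x.data.shape
        q = ad.transpose(ad.reshape(self.q(x), (n, N, self.heads, self.head_dim)),
                         (0, 2, 1, 3))
        if self.sr_ratio > 1:
            xm = _tokens_to_map(x, h, w)
            xm = self.sr(xm)
            _, _, hs, ws = xm.data.shape
            kv_in = self.norm(ad.transpose(ad.reshape(xm, (n, c, hs * ws)), (0, 2, 1)))
        else:
            kv_in = x
        Nk = kv_in.data.shape[1]
        kv = ad.reshape(self.kv(kv_in), (n, Nk, 2, self.heads, self.head_dim))
        kv = ad.transpose(kv, (2, 0, 3, 1, 4))
        k = _index0(kv, 0)  # (n, heads, Nk, head_dim)
        v = _index0(kv, 1)
        attn = ad.softmax(ad.mul(ad.matmul(q, ad.transpose(k, (0, 1, 3, 2))), self.scale))
        out = ad.matmul(attn, v)  # (n, heads, N, head_dim)
        out = ad.reshape(ad.transpose(out, (0, 2, 1, 3)), (n, N, c))
        return self.proj(out)


def _index0(t, i: int):
    """Select index i along axis 0 (differentiable slice)."""
    data = t.data[i]

    def bwd(g):
        full = np.zeros_like(t.data)
        full[i] = g
        ad._accum(t, full)

    return ad._make(data, (t,), bwd)


class MixFFN(nn.Module):
    """Linear -> depthwise 3x3 conv -> GELU -> Linear."""

    def __init__(self, dim: int, hidden: int):
        super().__init__()
        self.fc1 = nn.Linear(dim, hidden)
        self.dw = nn.Conv2d(hidden, hidden, 3, padding=1, groups=hidden)
        self.fc2 = nn.Linear(hidden, dim)

    def forward(self, x, h: int, w: int):
        x = self.fc1(x)
        x = _tokens_to_map(x, h, w)
        x = self.dw(x)
        n, c, _, _ = x.data.shape
        x = ad.transpose(ad.reshape(x, (n, c, h * w)), (0, 2, 1))
        return self.fc2(ad.gelu(x))


class Block(nn.Module):
    def __init__(self, dim: int, heads: int, mlp_ratio: int, sr_ratio: int):
        super().__init__()
        self.norm1 = nn.LayerNorm(dim)
        self.attn = SRAttention(dim, heads, sr_ratio)
        self.norm2 = nn.LayerNorm(dim)
        self.ffn = MixFFN(dim, dim * mlp_ratio)

    def forward(self, x, h: int, w: int):
        x = ad.add(x, self.attn(self.norm1(x), h, w))
        x = ad.add(x, self.ffn(self.norm2(x), h, w))
        return x


class PVTv2(nn.Module):
    """The b2 capacity by default; smaller settings exist for smoke tests."""

    def __init__(self, embed_dims=(64, 128, 320, 512), depths=(3, 4, 6, 3),
                 heads=(1, 2, 5, 8), mlp_ratios=(8, 8, 4, 4),
                 sr_ratios=(8, 4, 2, 1)):
        super().__init__()
        from . import BackboneSpec
        self.spec = BackboneSpec("pvt_v2_b2", tuple(embed_dims))
        self.patch_embeds = []
        self.stages = []
        self.norms = []
        in_ch = 3
        for i, dim in enumerate(embed_dims):
            patch, stride = (7, 4) if i == 0 else (3, 2)
            self.patch_embeds.append(OverlapPatchEmbed(in_ch, dim, patch, stride))
            self.stages.append([Block(dim, heads[i], mlp_ratios[i], sr_ratios[i])
                                for _ in range(depths[i])])
            self.norms.append(nn.LayerNorm(dim))
            in_ch = dim

    def forward(self, x):
        maps = []
        for embed, blocks, norm in zip(self.patch_embeds, self.stages, self.norms):
            tokens, h, w = embed(x)
            for blk in blocks:
                tokens = blk(tokens, h, w)
            tokens = norm(tokens)
            x = _tokens_to_map(tokens, h, w)
            maps.append(x)
        return maps
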