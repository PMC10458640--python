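"""End-to-end model assembly, ablation lattice and analytic parameter counts.

The full forward path is:

    pyramid S1..S4 -> FEB on S2/S3/S4 -> PPD -> global map G (stride 8)
    -> mixing module -> per-channel gate -> gated G -> mask head -> mask

Partial configurations (the ablation lattice) stay runnable by two rules:

* without the PPD, all available maps (a 1x1+BN projection of S4, plus any
  FEB outputs) are bilinearly resized to stride 8 and summed into G;
* without the mixer, G feeds the mask head directly (equivalent to a
  constant all-ones gate).

``ablation_rows()`` yields the cumulative chain backbone -> +FEB1 -> +FEB2
-> +FEB3 -> +FEB123+PPD -> full, and ``analytic_param_deltas()`` computes
from kernel/channel arithmetic how many parameters each step must add — the
PPD step also replaces the S4 projection, which the arithmetic accounts for.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from . import nn
from .backbones import build_backbone, BackboneSpec, extract_pyramid
from .config import ModelConfig
from .feb import FEB, FEBConfig, BasicConv
from .mixer import MixingModule, MaskHead, apply_gate, stride8_kernel
from .ppd import PPD


class MMNet(nn.Module):
    """Mixing-module segmentation network (use :func:`build_model`)."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        spec = BackboneSpec(cfg.backbone.name, tuple(cfg.backbone.out_channels),
                            pretrained=cfg.backbone.pretrained)
        backbone_seed = int(nn._rng().integers(2 ** 31))
        self.backbone = build_backbone(spec, seed=backbone_seed,
                                       checkpoint=cfg.backbone.checkpoint)
        ch = spec.out_channels
        cg = cfg.feb.out_channels
        flags = cfg.ablation

        feb_in = [ch[0] if cfg.feb1_on_s1 else ch[1], ch[2], ch[3]]
        self.feb1 = self._make_feb(feb_in[0], cg) if flags.feb1 else None
        self.feb2 = self._make_feb(feb_in[1], cg) if flags.feb2 else None
        self.feb3 = self._make_feb(feb_in[2], cg) if flags.feb3 else None

        if flags.ppd:
            # PPD needs maps at all three levels; plain projections stand in
            # for disabled FEBs
            self.lvl_proj = [
                None if (self.feb1 and not cfg.feb1_on_s1) else self._proj(ch[1], cg),
                None if self.feb2 else self._proj(ch[2], cg),
                None if self.feb3 else self._proj(ch[3], cg),
            ]
            self.ppd = PPD(cg, cfg.ppd.out_channels, dilation=cfg.ppd.dilation,
                           batch_norm=cfg.feb.batch_norm)
            self.proj4 = None
            g_channels = cfg.ppd.out_channels
        else:
            self.lvl_proj = [None, None, None]
            self.ppd = None
            self.proj4 = self._proj(ch[3], cg)
            g_channels = cg

        if flags.mixer:
            mix_cfg = cfg.mixer.to_mixer_config()
            if mix_cfg.operate_resolution == "stride8":
                s8 = cfg.image_size // 8
                k = stride8_kernel(mix_cfg, (s8, s8))
                mix_cfg = type(mix_cfg)(depth=mix_cfg.depth, dim=mix_cfg.dim,
                                        kernel_size=k,
                                        patch_size=mix_cfg.patch_size,
                                        operate_resolution="stride8")
            self.mixer = MixingModule(g_channels, mix_cfg,
                                      adapt_channels=(mix_cfg.dim != g_channels))
        else:
            self.mixer = None
        self.mask_head = MaskHead(g_channels)

    def _make_feb(self, cin, cout):
        return FEB(FEBConfig(cin, cout, tuple(self.cfg.feb.dilation_rates),
                             batch_norm=self.cfg.feb.batch_norm))

    def _proj(self, cin, cout):
        return BasicConv(cin, cout, 1, batch_norm=self.cfg.feb.batch_norm)

    def forward(self, x):
        x = x if isinstance(x, ad.Tensor) else ad.Tensor(x)
        n, _, H, W = x.data.shape
        pyramid = extract_pyramid(x, self.backbone)
        s1, s2, s3, s4 = pyramid.maps
        cfg = self.cfg
        s8_hw = s2.data.shape[-2:]

        enhanced = []  # maps feeding the stride-8 sum in the no-PPD path
        r = {}
        if self.feb1 is not None:
            r["f1"] = self.feb1(s1 if cfg.feb1_on_s1 else s2)
        if self.feb2 is not None:
            r["f2"] = self.feb2(s3)
        if self.feb3 is not None:
            r["f3"] = self.feb3(s4)

        if self.ppd is not None:
            r2 = r["f1"] if (self.feb1 and not cfg.feb1_on_s1) else self.lvl_proj[0](s2)
            r3 = r["f2"] if self.feb2 else self.lvl_proj[1](s3)
            r4 = r["f3"] if self.feb3 else self.lvl_proj[2](s4)
            g = self.ppd(r2, r3, r4)
        else:
            g = ad.resize_bilinear(self.proj4(s4), s8_hw)
            for fmap in r.values():
                g = ad.add(g, ad.resize_bilinear(fmap, s8_hw))

        if self.mixer is not None:
            gate = self.mixer(g, input_hw=(H, W))
            g = apply_gate(g, gate)
        return self.mask_head(g, (H, W))


def build_model(cfg: ModelConfig, seed: int = 0) -> MMNet:
    with nn.init_rng(np.random.default_rng([seed, 0x33])):
        return MMNet(cfg)


# ---------------------------------------------------------------------------
# ablation lattice
# ---------------------------------------------------------------------------

ABLATION_ROWS = ("backbone", "feb1", "feb2", "feb3", "ppd", "full")


def ablation_row_config(row: str, base: ModelConfig) -> ModelConfig:
    """Cumulative Table-style ablation rows built from a base config."""
    import copy
    cfg = copy.deepcopy(base)
    order = {name: i for i, name in enumerate(ABLATION_ROWS)}
    if row not in order:
        raise ValueError(f"unknown ablation row {row!r}; choose from {ABLATION_ROWS}")
    i = order[row]
    cfg.ablation.feb1 = i >= 1
    cfg.ablation.feb2 = i >= 2
    cfg.ablation.feb3 = i >= 3
    cfg.ablation.ppd = i >= 4
    cfg.ablation.mixer = i >= 5
    return cfg


# -- analytic parameter arithmetic ------------------------------------------

def _conv_params(cin, cout, kh, kw=None, bias=True):
    kw = kh if kw is None else kw
    return cout * cin * kh * kw + (cout if bias else 0)


def _basic_conv_params(cin, cout, kh, kw=None, bn=True):
    # BasicConv: conv without bias when BN is present; BN adds gamma+beta
    return _conv_params(cin, cout, kh, kw, bias=not bn) + (2 * cout if bn else 0)


def feb_param_count(cin: int, cout: int, rates, bn: bool = True) -> int:
    total = _basic_conv_params(cin, cout, 1, bn=bn)  # branch0
    for i, rate in enumerate(rates):
        k = 2 * i + 3
        total += _basic_conv_params(cin, cout, 1, bn=bn)
        total += _basic_conv_params(cout, cout, 1, k, bn=bn)
        total += _basic_conv_params(cout, cout, k, 1, bn=bn)
        total += _basic_conv_params(cout, cout, 3, bn=bn)
    n_branch = 1 + len(rates)
    total += _basic_conv_params(n_branch * cout, cout, 3, bn=bn)  # fuse
    total += _basic_conv_params(cin, cout, 1, bn=bn)              # shortcut
    return total


def ppd_param_count(c: int, cout: int, bn: bool = True) -> int:
    total = 4 * _basic_conv_params(c, c, 3, bn=bn)        # three ups + r4 cat
    total += _basic_conv_params(2 * c, 2 * c, 3, bn=bn)   # c3 upsample conv
    total += _basic_conv_params(2 * c, 2 * c, 3, bn=bn)   # concat3
    total += _basic_conv_params(3 * c, 3 * c, 3, bn=bn)   # concat2
    total += _basic_conv_params(3 * c, cout, 3, bn=bn)    # dilated fuse
    total += _conv_params(cout, cout, 1)                  # 1x1 out
    return total


def mixer_param_count(cin: int, depth: int, dim: int, kernel: int,
                      patch: int) -> int:
    total = 0
    if dim != cin:
        total += _conv_params(cin, dim, 1)       # input adapter
        total += dim * cin + cin                 # gate projection
    total += _conv_params(dim, dim, patch) + 2 * dim       # patch embed + LN
    per_block = (dim * kernel * kernel + dim) + 2 * dim \
        + _conv_params(dim, dim, 1) + 2 * dim
    return total + depth * per_block


def analytic_param_deltas(cfg: ModelConfig) -> dict[str, int]:
    """Expected parameter-count increments along the ablation chain.

    Keys are the rows added relative to their predecessor; the PPD step both
    adds the decoder and removes the standalone S4 projection.
    """
    ch = tuple(cfg.backbone.out_channels)
    cg = cfg.feb.out_channels
    bn = cfg.feb.batch_norm
    rates = tuple(cfg.feb.dilation_rates)
    proj4 = _basic_conv_params(ch[3], cg, 1, bn=bn)
    mix = cfg.mixer
    s8 = cfg.image_size // 8
    kernel = mix.kernel_size
    if mix.operate_resolution == "stride8":
        from .mixer import MixerConfig
        kernel = stride8_kernel(MixerConfig(depth=mix.depth, dim=mix.dim,
                                            kernel_size=mix.kernel_size,
                                            patch_size=mix.patch_size,
                                            operate_resolution="stride8"),
                                (s8, s8))
    return {
        "feb1": feb_param_count(ch[0] if cfg.feb1_on_s1 else ch[1], cg, rates, bn),
        "feb2": feb_param_count(ch[2], cg, rates, bn),
        "feb3": feb_param_count(ch[3], cg, rates, bn),
        "ppd": ppd_param_count(cg, cfg.ppd.out_channels, bn) - proj4,
        "full": mixer_param_count(cfg.ppd.out_channels, mix.depth, mix.dim,
                                  kernel, mix.patch_size),
    }
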