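"""Parallel partial decoder: fuse the three deepest enhanced maps.

The decoder is "partial" because level-1 features (stride 4) are discarded
entirely — they are expensive and contribute little — and "parallel" because
deeper context is multiplied into shallower maps while the maps are also
concatenated progressively.  With enhanced maps R2, R3, R4 at strides
8/16/32 (shared channel count C):

    r3' = conv(up2(R4)) * R3
    r2' = conv(up4(R4)) * conv(up2(R3)) * R2
    c3  = conv(cat(r3', conv(up2(R4))))
    c2  = conv(cat(r2', conv(up2(c3))))
    G   = conv1x1(conv3x3_dilated(c2))

The output (the "global feature map") lives at R2's stride-8 resolution with
``out_channels`` channels.  The fusion 3x3 carries a configurable dilation
(default 2) to widen its view without extra parameters.
"""

from __future__ import annotations

from . import autodiff as ad
from . import nn
from .feb import BasicConv


class PPD(nn.Module):
    def __init__(self, channels: int, out_channels: int, dilation: int = 2,
                 batch_norm: bool = True):
        super().__init__()
        self.channels = channels
        self.out_channels = out_channels
        bn = batch_norm
        c = channels
        self.up_r4_to_r3 = BasicConv(c, c, 3, padding=1, batch_norm=bn)
        self.up_r4_to_r2 = BasicConv(c, c, 3, padding=1, batch_norm=bn)
        self.up_r3_to_r2 = BasicConv(c, c, 3, padding=1, batch_norm=bn)
        self.up_r4_cat = BasicConv(c, c, 3, padding=1, batch_norm=bn)
        self.up_c3_cat = BasicConv(2 * c, 2 * c, 3, padding=1, batch_norm=bn)
        self.concat3 = BasicConv(2 * c, 2 * c, 3, padding=1, batch_norm=bn)
        self.concat2 = BasicConv(3 * c, 3 * c, 3, padding=1, batch_norm=bn)
        self.fuse = BasicConv(3 * c, out_channels, 3, padding=dilation,
                              dilation=dilation, batch_norm=bn)
        self.out = nn.Conv2d(out_channels, out_channels, 1)

    @staticmethod
    def _validate(r2, r3, r4, channels):
        shapes = [t.data.shape for t in (r2, r3, r4)]
        if any(s[1] != channels for s in shapes):
            raise ValueError(
                f"PPD expects {channels} channels on all inputs, got "
                f"{[s[1] for s in shapes]}")
        for (deep, shallow) in ((shapes[2], shapes[1]), (shapes[1], shapes[0])):
            if shallow[2] != 2 * deep[2] or shallow[3] != 2 * deep[3]:
                raise ValueError(
                    f"PPD inputs must form a 2x spatial chain; got {shapes}")

    def forward(self, r2, r3, r4):
        """r2/r3/r4: enhanced maps at strides 8/16/32 (shallow to deep)."""
        self._validate(r2, r3, r4, self.channels)
        h3 = r3.data.shape[-2:]
        h2 = r2.data.shape[-2:]
        up = ad.resize_bilinear
        r3p = ad.mul(self.up_r4_to_r3(up(r4, h3)), r3)
        r2p = ad.mul(ad.mul(self.up_r4_to_r2(up(r4, h2)),
                            self.up_r3_to_r2(up(r3, h2))), r2)
        c3 = self.concat3(ad.concat([r3p, self.up_r4_cat(up(r4, h3))], axis=1))
        c2 = self.concat2(ad.concat([r2p, self.up_c3_cat(up(c3, h2))], axis=1))
        return self.out(self.fuse(c2))


def ppd_aggregate(r2, r3, r4, weights: PPD):
    """Functional wrapper: aggregate enhanced maps into the global feature map."""
    return weights(r2, r3, r4)
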