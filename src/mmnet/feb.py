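"""Feature-enhancing block: a multi-branch dilated receptive-field block.

One FEB instance refines one encoder level without changing its spatial
size. Four parallel branches look at progressively larger neighbourhoods —
a 1x1 branch plus three branches of factorized (1xk, kx1) convolutions
followed by a 3x3 convolution whose dilation grows branch to branch — then
the branch outputs are concatenated, fused by a 3x3 convolution and added to
a 1x1 shortcut of the input.  Growing kernel *and* dilation makes each
branch's effective receptive field strictly larger than the previous one,
which is what lets the block pick up polyp context at several scales at
once.

Default dilation rates are (3, 5, 7); appending an extra rate adds a fourth
dilated branch with the next odd factorized kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import autodiff as ad
from . import nn


@dataclass(frozen=True)
class FEBConfig:
    in_channels: int
    out_channels: int
    dilation_rates: tuple[int, ...] = (3, 5, 7)
    batch_norm: bool = True  # False gives the batch-size-1-safe variant

    def __post_init__(self):
        if any(b >= a for a, b in zip(self.dilation_rates[1:], self.dilation_rates)):
            raise ValueError("dilation_rates must be strictly increasing")


class BasicConv(nn.Module):
    """Conv + optional BatchNorm + optional ReLU."""

    def __init__(self, in_ch, out_ch, kernel, padding=0, dilation=1,
                 batch_norm=True, act=True):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, kernel, padding=padding,
                              dilation=dilation, bias=not batch_norm)
        self.norm = nn.BatchNorm2d(out_ch) if batch_norm else nn.Identity()
        self.act = nn.ReLU() if act else nn.Identity()

    def forward(self, x):
        return self.act(self.norm(self.conv(x)))


class FEB(nn.Module):
    def __init__(self, cfg: FEBConfig):
        super().__init__()
        self.cfg = cfg
        cin, cout, bn = cfg.in_channels, cfg.out_channels, cfg.batch_norm
        self.branch0 = BasicConv(cin, cout, 1, batch_norm=bn)
        self.branches = []
        for i, rate in enumerate(cfg.dilation_rates):
            k = 2 * i + 3  # 3, 5, 7, ...
            self.branches.append(nn.Sequential(
                BasicConv(cin, cout, 1, batch_norm=bn),
                BasicConv(cout, cout, (1, k), padding=(0, k // 2), batch_norm=bn),
                BasicConv(cout, cout, (k, 1), padding=(k // 2, 0), batch_norm=bn),
                BasicConv(cout, cout, 3, padding=rate, dilation=rate, batch_norm=bn),
            ))
        n_branch = 1 + len(cfg.dilation_rates)
        self.fuse = BasicConv(n_branch * cout, cout, 3, padding=1,
                              batch_norm=bn, act=False)
        self.shortcut = BasicConv(cin, cout, 1, batch_norm=bn, act=False)

    def forward(self, x):
        if x.data.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"FEB expects {self.cfg.in_channels} input channels, "
                f"got {x.data.shape[1]}")
        outs = [self.branch0(x)] + [b(x) for b in self.branches]
        fused = self.fuse(ad.concat(outs, axis=1))
        return ad.relu(ad.add(fused, self.shortcut(x)))

    def receptive_fields(self) -> list[int]:
        """Analytic effective receptive field (one side) per branch."""
        fields = [1]
        for i, rate in enumerate(self.cfg.dilation_rates):
            k = 2 * i + 3
            # 1xk then kx1 then dilated 3x3: rf = 1 + (k-1) + (k-1)... per axis
            rf = 1 + (k - 1) + (k - 1) + 2 * rate
            fields.append(rf)
        return fields


def feb_forward(feature_map, cfg: FEBConfig, weights: FEB):
    """Functional wrapper over a built FEB (validates the channel contract)."""
    if weights.cfg != cfg:
        raise ValueError("weights were built for a different FEBConfig")
    return weights(feature_map)
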