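"""Uniform contract for pyramid feature encoders.

Every backbone maps an N x 3 x H x W batch (H, W divisible by 32) to four
feature maps S1..S4 at strides 4/8/16/32 with declared channel counts, so the
decoder stack is indifferent to whether the encoder is the full PVTv2-b2
transformer or the small strided-convolution stand-in used for CPU tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .. import nn
from ..autodiff import Tensor

STRIDES = (4, 8, 16, 32)

PVT_V2_B2_CHANNELS = (64, 128, 320, 512)


@dataclass(frozen=True)
class BackboneSpec:
    name: str  # "pvt_v2_b2" | "tiny_test"
    out_channels: tuple[int, int, int, int]
    strides: tuple[int, int, int, int] = STRIDES
    pretrained: bool = False

    def __post_init__(self):
        if self.name not in ("pvt_v2_b2", "tiny_test"):
            raise ValueError(f"unknown backbone name {self.name!r}")
        if tuple(self.strides) != STRIDES:
            raise ValueError(f"strides must be {STRIDES}")
        if len(self.out_channels) != 4 or any(c <= 0 for c in self.out_channels):
            raise ValueError("out_channels must be 4 positive ints")
        if self.pretrained and self.name != "pvt_v2_b2":
            raise ValueError("pretrained weights exist only for pvt_v2_b2")


@dataclass
class FeaturePyramid:
    """The four multi-scale encoder outputs S1..S4."""

    maps: list  # list of 4 Tensors, NCHW
    spec: BackboneSpec = None

    def __post_init__(self):
        if len(self.maps) != 4:
            raise ValueError("a feature pyramid has exactly 4 levels")

    def __iter__(self):
        return iter(self.maps)

    def __getitem__(self, i):
        return self.maps[i]


def _validate_input(x: np.ndarray | Tensor):
    shape = x.data.shape if isinstance(x, Tensor) else x.shape
    if len(shape) != 4 or shape[1] != 3:
        raise ValueError(f"expected N x 3 x H x W input, got {shape}")
    _, _, H, W = shape
    for dim, name in ((H, "height"), (W, "width")):
        if dim % 32:
            raise ValueError(
                f"input {name} {dim} is not divisible by 32; pad the batch first")


def extract_pyramid(image_batch, backbone: nn.Module) -> FeaturePyramid:
    """Run an encoder and validate the pyramid contract."""
    _validate_input(image_batch)
    x = image_batch if isinstance(image_batch, Tensor) else Tensor(image_batch)
    maps = backbone(x)
    spec = backbone.spec
    _, _, H, W = x.data.shape
    for m, (fmap, stride, ch) in enumerate(zip(maps, spec.strides, spec.out_channels)):
        expect = (x.data.shape[0], ch, H // stride, W // stride)
        if fmap.data.shape != expect:
            raise AssertionError(
                f"backbone {spec.name} level {m + 1}: got {fmap.data.shape}, "
                f"expected {expect}")
    return FeaturePyramid(maps=list(maps), spec=spec)


class TinyBackbone(nn.Module):
    """Four-stage strided convolutional encoder for CPU-scale tests.

    Stage 1 is two stride-2 convs (stride 4 total); stages 2-4 are single
    stride-2 conv blocks. Channel counts are configurable so the decoder can
    be exercised at either toy or paper-like widths.
    """

    def __init__(self, out_channels=(8, 16, 32, 64)):
        super().__init__()
        c1, c2, c3, c4 = out_channels
        self.spec = BackboneSpec("tiny_test", tuple(out_channels))
        self.stage1 = nn.Sequential(
            nn.Conv2d(3, c1, 3, stride=2, padding=1), nn.BatchNorm2d(c1), nn.ReLU(),
            nn.Conv2d(c1, c1, 3, stride=2, padding=1), nn.BatchNorm2d(c1), nn.ReLU(),
        )
        self.stage2 = nn.Sequential(
            nn.Conv2d(c1, c2, 3, stride=2, padding=1), nn.BatchNorm2d(c2), nn.ReLU())
        self.stage3 = nn.Sequential(
            nn.Conv2d(c2, c3, 3, stride=2, padding=1), nn.BatchNorm2d(c3), nn.ReLU())
        self.stage4 = nn.Sequential(
            nn.Conv2d(c3, c4, 3, stride=2, padding=1), nn.BatchNorm2d(c4), nn.ReLU())

    def forward(self, x):
        s1 = self.stage1(x)
        s2 = self.stage2(s1)
        s3 = self.stage3(s2)
        s4 = self.stage4(s3)
        return [s1, s2, s3, s4]


def make_tiny_backbone(seed: int, out_channels=(8, 16, 32, 64)):
    """Seeded tiny encoder; returns (module, spec)."""
    if any(c < 4 for c in out_channels):
        raise ValueError("tiny backbone channels must all be >= 4")
    with nn.init_rng(np.random.default_rng([seed, 0x7e5])):
        model = TinyBackbone(out_channels)
    return model, model.spec


def build_backbone(spec: BackboneSpec, seed: int = 0, checkpoint: str | None = None):
    """Construct a backbone from its spec (optionally loading .npz weights)."""
    if spec.name == "tiny_test":
        model, _ = make_tiny_backbone(seed, spec.out_channels)
    else:
        from .pvt_v2 import PVTv2
        with nn.init_rng(np.random.default_rng([seed, 0x9e2])):
            model = PVTv2()
        if spec.pretrained:
            if checkpoint is None:
                raise ValueError(
                    "pretrained=True requires a checkpoint path to an .npz "
                    "state dict (no weights are bundled)")
            state = dict(np.load(checkpoint))
            model.load_state_dict(state)
    return model
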