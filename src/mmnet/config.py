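"""Configuration dataclasses and YAML round-tripping.

``default_config()`` carries the published training recipe: 352x352 inputs,
multiscale factors {0.75, 1, 1.25}, rotation/flip augmentation, Adam at
1e-4 with polynomial decay, 60 epochs, batch 16, and mixer hyperparameters
depth 20 / dim 64 / kernel 28 / patch 9.  ``tiny_config()`` shrinks every
axis (96 input, tiny backbone, depth 2 / dim 16 / kernel 7 / patch 4) for
CPU-scale smoke runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, is_dataclass

import yaml

from .backbones import PVT_V2_B2_CHANNELS
from .mixer import MixerConfig


@dataclass
class BackboneConfig:
    name: str = "pvt_v2_b2"
    out_channels: tuple = PVT_V2_B2_CHANNELS  # fixed for pvt_v2_b2
    pretrained: bool = False
    checkpoint: str | None = None


@dataclass
class FEBSettings:
    out_channels: int = 64  # kept equal to mixer.dim so the gate applies directly
    dilation_rates: tuple = (3, 5, 7)
    batch_norm: bool = True


@dataclass
class PPDSettings:
    dilation: int = 2
    out_channels: int = 64


@dataclass
class MixerSettings:
    enabled: bool = True
    depth: int = 20
    dim: int = 64
    kernel_size: int = 28
    patch_size: int = 9
    operate_resolution: str = "input"

    def to_mixer_config(self) -> MixerConfig:
        return MixerConfig(depth=self.depth, dim=self.dim,
                           kernel_size=self.kernel_size,
                           patch_size=self.patch_size,
                           operate_resolution=self.operate_resolution)


@dataclass
class AblationFlags:
    """Which blocks exist; feb1/2/3 are the FEB instances on S2/S3/S4."""

    feb1: bool = True
    feb2: bool = True
    feb3: bool = True
    ppd: bool = True
    mixer: bool = True


@dataclass
class ModelConfig:
    image_size: int = 352
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    feb: FEBSettings = field(default_factory=FEBSettings)
    ppd: PPDSettings = field(default_factory=PPDSettings)
    mixer: MixerSettings = field(default_factory=MixerSettings)
    ablation: AblationFlags = field(default_factory=AblationFlags)
    # alternate reading of the first-FEB ablation row: apply FEB1 to the
    # stride-4 level S1 instead of being the first instance (on S2)
    feb1_on_s1: bool = False


@dataclass
class TrainConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    batch_size: int = 16
    epochs: int = 60
    base_lr: float = 1e-4
    multiscale_factors: tuple = (0.75, 1.0, 1.25)
    augment: bool = True
    rotate_max_deg: float = 90.0
    lr_decay_kind: str = "poly"  # "poly" (power 0.9) | "step" (x0.1)
    lr_poly_power: float = 0.9
    lr_step_factor: float = 0.1
    seed: int = 0
    max_iters: int | None = None  # stop after this many optimizer steps
    loss_reduction: str = "mean"

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if any(f <= 0 for f in self.multiscale_factors):
            raise ValueError("multiscale factors must be positive")


def default_config() -> TrainConfig:
    return TrainConfig()


def tiny_config(seed: int = 0) -> TrainConfig:
    """CPU-scale preset: tiny backbone, 96px images, shallow narrow mixer."""
    model = ModelConfig(
        image_size=96,
        backbone=BackboneConfig(name="tiny_test", out_channels=(8, 16, 32, 64)),
        feb=FEBSettings(out_channels=16),
        ppd=PPDSettings(out_channels=16),
        mixer=MixerSettings(depth=2, dim=16, kernel_size=7, patch_size=4),
    )
    # toy-scale datasets fit in one batch; full-batch Adam with a larger
    # step and a gentle decay converges much faster at this model size
    return TrainConfig(model=model, batch_size=8, epochs=200, base_lr=5e-3,
                       lr_poly_power=0.3, multiscale_factors=(1.0,),
                       augment=False, seed=seed)


def _to_plain(obj):
    if is_dataclass(obj):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def save_yaml(cfg, path):
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(cfg), fh, sort_keys=False)


def _dict_to_dataclass(cls, data: dict):
    kwargs = {}
    hints = {f.name: f.type for f in cls.__dataclass_fields__.values()} \
        if hasattr(cls, "__dataclass_fields__") else {}
    nested = {"model": ModelConfig, "backbone": BackboneConfig, "feb": FEBSettings,
              "ppd": PPDSettings, "mixer": MixerSettings, "ablation": AblationFlags}
    for key, value in data.items():
        if key in nested and isinstance(value, dict):
            kwargs[key] = _dict_to_dataclass(nested[key], value)
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_yaml(path, cls=TrainConfig):
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return _dict_to_dataclass(cls, data)
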