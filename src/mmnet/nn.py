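"""Neural-network layers, parameter management and the Adam optimizer.

Layers mirror the conventional conv-net vocabulary (Conv2d, BatchNorm2d,
LayerNorm, Linear, Sequential) but run on the package's NumPy autodiff core.
Parameter initialization draws from an explicit seeded generator supplied via
the ``init_rng`` context manager, so every model build is reproducible from a
single integer seed.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

_RNG_STACK: list[np.random.Generator] = []


@contextmanager
def init_rng(rng: np.random.Generator | int):
    """Push the generator used for parameter initialization."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    _RNG_STACK.append(rng)
    try:
        yield rng
    finally:
        _RNG_STACK.pop()


def _rng() -> np.random.Generator:
    if not _RNG_STACK:
        raise RuntimeError(
            "parameter initialization requires an active init_rng(seed) context")
    return _RNG_STACK[-1]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and state dicts."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    @staticmethod
    def _children(value, prefix):
        """Yield (name, Module) pairs, recursing into nested lists/tuples."""
        if isinstance(value, Module):
            yield prefix, value
        elif isinstance(value, (list, tuple)):
            for i, item in enumerate(value):
                yield from Module._children(item, f"{prefix}.{i}")

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            else:
                for cname, child in self._children(value, full):
                    yield from child.named_parameters(f"{cname}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in vars(self).values():
            for _, child in self._children(value, ""):
                yield from child.modules()

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if name.startswith("buf_") and isinstance(value, np.ndarray):
                yield full, value
            else:
                for cname, child in self._children(value, full):
                    yield from child.named_buffers(f"{cname}.")

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        missing = (set(own) | set(bufs)) - set(state)
        extra = set(state) - (set(own) | set(bufs))
        if missing or extra:
            raise KeyError(
                f"state dict mismatch: missing={sorted(missing)[:5]} "
                f"extra={sorted(extra)[:5]}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=np.float64).copy()
        for name, b in bufs.items():
            b[...] = state[name]


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return ad.relu(x)


class GELU(Module):
    def forward(self, x):
        return ad.gelu(x)


def _kaiming(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int | tuple,
                 stride: int = 1, padding=0, dilation: int = 1, groups: int = 1,
                 bias: bool = True):
        super().__init__()
        kh, kw = (kernel_size, kernel_size) if isinstance(kernel_size, int) else kernel_size
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = (kh, kw)
        self.stride = stride
        self.padding = padding
        self.dilation = dilation
        self.groups = groups
        fan_in = (in_channels // groups) * kh * kw
        rng = _rng()
        self.weight = Parameter(_kaiming(rng, (out_channels, in_channels // groups, kh, kw), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        return ad.conv2d(x, self.weight, self.bias, stride=self.stride,
                         padding=self.padding, dilation=self.dilation,
                         groups=self.groups)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        rng = _rng()
        self.weight = Parameter(rng.normal(0.0, 0.02, size=(in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x):
        out = ad.matmul(x, self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    """Standard batch norm with running statistics (NCHW)."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones((1, num_features, 1, 1)))
        self.bias = Parameter(np.zeros((1, num_features, 1, 1)))
        self.buf_running_mean = np.zeros(num_features)
        self.buf_running_var = np.ones(num_features)

    def forward(self, x):
        if self.training:
            out = ad.normalize(x, self.weight, self.bias, axes=(0, 2, 3), eps=self.eps)
            m = x.data.mean(axis=(0, 2, 3))
            v = x.data.var(axis=(0, 2, 3))
            self.buf_running_mean += self.momentum * (m - self.buf_running_mean)
            self.buf_running_var += self.momentum * (v - self.buf_running_var)
            return out
        inv = 1.0 / np.sqrt(self.buf_running_var + self.eps)
        scale = self.weight.data * inv.reshape(1, -1, 1, 1)
        shift = self.bias.data - self.weight.data * (
            self.buf_running_mean.reshape(1, -1, 1, 1) * inv.reshape(1, -1, 1, 1))
        # eval mode: a fixed affine map w.r.t. the running statistics, but the
        # scale/shift still depend on the learnable gamma/beta
        xhat = ad.affine(x, inv.reshape(1, -1, 1, 1),
                         -self.buf_running_mean.reshape(1, -1, 1, 1) * inv.reshape(1, -1, 1, 1))
        return ad.add(ad.mul(xhat, self.weight), self.bias)


class LayerNorm2d(Module):
    """Layer norm over the channel axis of an NCHW map (per spatial site)."""

    def __init__(self, num_channels: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones((1, num_channels, 1, 1)))
        self.bias = Parameter(np.zeros((1, num_channels, 1, 1)))

    def forward(self, x):
        return ad.normalize(x, self.weight, self.bias, axes=(1,), eps=self.eps)


class LayerNorm(Module):
    """Layer norm over the last axis (token representations)."""

    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))

    def forward(self, x):
        return ad.normalize(x, self.weight, self.bias, axes=(-1,), eps=self.eps)


class Adam:
    """Adam with the conventional defaults (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad * p.grad - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
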