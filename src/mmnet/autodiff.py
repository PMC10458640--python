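"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operations the segmentation network needs: grouped /
dilated 2-D convolution, layer and batch normalization, GELU/ReLU/sigmoid,
softmax, batched matmul, bilinear resizing, padding (zero and reflect),
reductions and elementwise arithmetic.  Everything is float64 throughout,
which keeps finite-difference gradient checks tight and makes forward passes
bit-reproducible across runs.

A :class:`Tensor` records its parents and a backward closure; calling
``backward()`` on a scalar runs the tape in reverse topological order.
``no_grad()`` disables tape construction for inference.
"""

from __future__ import annotations

import math
from contextlib import contextmanager
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
from scipy import fft as sfft
from scipy.special import erf

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Context manager that disables graph construction."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # ---- construction helpers -------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ---- autodiff machinery ---------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---- operator sugar --------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / other)

    def __neg__(self):
        return mul(self, -1.0)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes if len(axes) > 1 else axes[0])


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nextra = grad.ndim - len(shape)
    if nextra:
        grad = grad.sum(axis=tuple(range(nextra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray):
    if not t.requires_grad:
        return
    g = _unbroadcast(np.asarray(g, dtype=np.float64), t.data.shape)
    if t.grad is None:
        t.grad = g.copy()
    else:
        t.grad += g


# ---------------------------------------------------------------------------
# elementwise arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data + b.data

    def bwd(g):
        _accum(a, g)
        _accum(b, g)

    return _make(out, (a, b), bwd)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data * b.data

    def bwd(g):
        _accum(a, g * b.data)
        _accum(b, g * a.data)

    return _make(out, (a, b), bwd)


def power(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    out = a.data ** exponent

    def bwd(g):
        _accum(a, g * exponent * a.data ** (exponent - 1.0))

    return _make(out, (a,), bwd)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out = np.exp(a.data)

    def bwd(g):
        _accum(a, g * out)

    return _make(out, (a,), bwd)


def log(a) -> Tensor:
    a = as_tensor(a)
    out = np.log(a.data)

    def bwd(g):
        _accum(a, g / a.data)

    return _make(out, (a,), bwd)


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def clamp(a, lo: float, hi: float) -> Tensor:
    """Clip values; gradient flows only through the interior."""
    a = as_tensor(a)
    out = np.clip(a.data, lo, hi)
    mask = (a.data >= lo) & (a.data <= hi)

    def bwd(g):
        _accum(a, g * mask)

    return _make(out, (a,), bwd)


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    out = a.data * mask

    def bwd(g):
        _accum(a, g * mask)

    return _make(out, (a,), bwd)


_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(a) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    a = as_tensor(a)
    cdf = 0.5 * (1.0 + erf(a.data / _SQRT2))
    out = a.data * cdf

    def bwd(g):
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * a.data * a.data)
        _accum(a, g * (cdf + a.data * pdf))

    return _make(out, (a,), bwd)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out = 1.0 / (1.0 + np.exp(-a.data))

    def bwd(g):
        _accum(a, g * out * (1.0 - out))

    return _make(out, (a,), bwd)


# ---------------------------------------------------------------------------
# reductions / reshaping
# ---------------------------------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            ax = axis if isinstance(axis, tuple) else (axis,)
            ax = tuple(x % a.data.ndim for x in ax)
            shape = [1 if i in ax else s for i, s in enumerate(a.data.shape)]
            g = g.reshape(shape)
        _accum(a, np.broadcast_to(g, a.data.shape))

    return _make(out, (a,), bwd)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[x % a.data.ndim] for x in ax]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out = a.data.reshape(shape)
    orig = a.data.shape

    def bwd(g):
        _accum(a, g.reshape(orig))

    return _make(out, (a,), bwd)


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    out = a.data.transpose(axes)
    inv = np.argsort(axes)

    def bwd(g):
        _accum(a, g.transpose(inv))

    return _make(out, (a,), bwd)


def concat(tensors: Sequence, axis: int = 1) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            _accum(t, g[tuple(idx)])

    return _make(out, tuple(ts), bwd)


def matmul(a, b) -> Tensor:
    """Batched matrix multiply with broadcasting over leading dims."""
    a, b = as_tensor(a), as_tensor(b)
    out = np.matmul(a.data, b.data)

    def bwd(g):
        _accum(a, np.matmul(g, np.swapaxes(b.data, -1, -2)))
        _accum(b, np.matmul(np.swapaxes(a.data, -1, -2), g))

    return _make(out, (a, b), bwd)


def softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        _accum(a, out * (g - dot))

    return _make(out, (a,), bwd)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize(a, gamma, beta, axes, eps: float = 1e-5) -> Tensor:
    """Normalize over `axes` (biased variance) then scale/shift.

    Shared kernel behind layer norm (axes=(1,) on NCHW, axes=(-1,) on tokens)
    and training-mode batch norm (axes=(0, 2, 3)).
    """
    a, gamma, beta = as_tensor(a), as_tensor(gamma), as_tensor(beta)
    ax = tuple(x % a.data.ndim for x in (axes if isinstance(axes, tuple) else (axes,)))
    mu = a.data.mean(axis=ax, keepdims=True)
    var = a.data.var(axis=ax, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (a.data - mu) * inv_std
    out = gamma.data * xhat + beta.data

    def bwd(g):
        _accum(gamma, g * xhat)
        _accum(beta, g)
        if a.requires_grad:
            dxhat = g * gamma.data
            m1 = dxhat.mean(axis=ax, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=ax, keepdims=True)
            _accum(a, inv_std * (dxhat - m1 - xhat * m2))

    return _make(out, (a, gamma, beta), bwd)


def affine(a, scale: np.ndarray, shift: np.ndarray) -> Tensor:
    """Elementwise `a * scale + shift` with constant (non-learned) arrays."""
    a = as_tensor(a)
    out = a.data * scale + shift

    def bwd(g):
        _accum(a, g * scale)

    return _make(out, (a,), bwd)


# ---------------------------------------------------------------------------
# padding
# ---------------------------------------------------------------------------

def pad2d(a, pads: tuple[int, int, int, int], mode: str = "constant") -> Tensor:
    """Pad the last two axes by (top, bottom, left, right)."""
    a = as_tensor(a)
    pt, pb, pl, pr = pads
    if pt == pb == pl == pr == 0:
        return a
    H, W = a.data.shape[-2:]
    if mode == "constant":
        width = [(0, 0)] * (a.data.ndim - 2) + [(pt, pb), (pl, pr)]
        out = np.pad(a.data, width)

        def bwd(g):
            idx = (Ellipsis, slice(pt, pt + H), slice(pl, pl + W))
            _accum(a, g[idx])

        return _make(out, (a,), bwd)
    if mode == "reflect":
        rows = np.pad(np.arange(H), (pt, pb), mode="reflect")
        cols = np.pad(np.arange(W), (pl, pr), mode="reflect")
        width = [(0, 0)] * (a.data.ndim - 2) + [(pt, pb), (pl, pr)]
        out = np.pad(a.data, width, mode="reflect")
        lin = (rows[:, None] * W + cols[None, :]).ravel()

        def bwd(g):
            lead = int(np.prod(a.data.shape[:-2], dtype=np.int64))
            g2 = g.reshape(lead, -1)
            gx = np.zeros((lead, H * W))
            np.add.at(gx, (np.arange(lead)[:, None], lin[None, :]), g2)
            _accum(a, gx.reshape(a.data.shape))

        return _make(out, (a,), bwd)
    raise ValueError(f"unknown pad mode {mode!r}")


# ---------------------------------------------------------------------------
# 2-D convolution (grouped, strided, dilated) via im2col
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int,
            dh: int, dw: int, groups: int) -> tuple[np.ndarray, int, int]:
    N, C, Hp, Wp = xp.shape
    khd, kwd = (kh - 1) * dh + 1, (kw - 1) * dw + 1
    v = np.lib.stride_tricks.sliding_window_view(xp, (khd, kwd), axis=(2, 3))
    v = v[:, :, ::sh, ::sw, ::dh, ::dw]  # (N, C, Ho, Wo, kh, kw)
    Ho, Wo = v.shape[2], v.shape[3]
    cols = np.ascontiguousarray(v.transpose(0, 1, 4, 5, 2, 3))
    cols = cols.reshape(N, groups, (C // groups) * kh * kw, Ho * Wo)
    return cols, Ho, Wo


def conv2d(x, weight, bias=None, stride: int | tuple = 1,
           padding: int | tuple = 0, dilation: int | tuple = 1,
           groups: int = 1) -> Tensor:
    """2-D cross-correlation. x: (N,Cin,H,W); weight: (Cout,Cin/groups,kh,kw).

    `padding` is an int, a (ph, pw) pair, or an explicit (top, bottom, left,
    right) 4-tuple (needed for "same" padding with even kernels).
    """
    x, weight = as_tensor(x), as_tensor(weight)
    if bias is not None:
        bias = as_tensor(bias)
    sh, sw = (stride, stride) if isinstance(stride, int) else stride
    dh, dw = (dilation, dilation) if isinstance(dilation, int) else dilation
    if isinstance(padding, int):
        pads = (padding, padding, padding, padding)
    elif len(padding) == 2:
        pads = (padding[0], padding[0], padding[1], padding[1])
    else:
        pads = tuple(padding)
    Cout, Cin_g, kh, kw = weight.data.shape
    N, Cin, H, W = x.data.shape
    if Cin != Cin_g * groups:
        raise ValueError(
            f"conv2d channel mismatch: input has {Cin} channels, "
            f"weight expects {Cin_g * groups}")
    pt, pb, pl, pr = pads
    width = [(0, 0), (0, 0), (pt, pb), (pl, pr)]
    xp = np.pad(x.data, width) if any(pads) else x.data
    parents = (x, weight) if bias is None else (x, weight, bias)

    # depthwise convolutions with large kernels (the mixer's spatial-mixing
    # convs) go through FFTs; im2col would materialize k*k copies of the map
    if (groups == Cin == Cout and sh == sw == dh == dw == 1 and kh * kw >= 64):
        out, bwd = _depthwise_fft(x, weight, bias, xp, pads, kh, kw)
        return _make(out, parents, bwd)

    cols, Ho, Wo = _im2col(xp, kh, kw, sh, sw, dh, dw, groups)
    wg = weight.data.reshape(groups, Cout // groups, Cin_g * kh * kw)
    out = np.matmul(wg[None], cols)  # (N, G, Cout/G, L)
    out = out.reshape(N, Cout, Ho, Wo)
    if bias is not None:
        out = out + bias.data.reshape(1, -1, 1, 1)

    def bwd(g):
        go = g.reshape(N, groups, Cout // groups, Ho * Wo)
        if bias is not None:
            _accum(bias, g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            # recompute cols rather than caching (bounds peak memory)
            xp_b = np.pad(x.data, width) if any(pads) else x.data
            cols_b, _, _ = _im2col(xp_b, kh, kw, sh, sw, dh, dw, groups)
            gw = np.matmul(go, np.swapaxes(cols_b, -1, -2)).sum(axis=0)
            _accum(weight, gw.reshape(weight.data.shape))
        if x.requires_grad:
            gcols = np.matmul(np.swapaxes(wg, -1, -2)[None], go)
            gcols = gcols.reshape(N, Cin, kh, kw, Ho, Wo)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                hi = i * dh
                for j in range(kw):
                    wj = j * dw
                    gxp[:, :, hi:hi + Ho * sh:sh, wj:wj + Wo * sw:sw] += gcols[:, :, i, j]
            if any(pads):
                gxp = gxp[:, :, pt:pt + H, pl:pl + W]
            _accum(x, gxp)

    return _make(out, parents, bwd)


def _depthwise_fft(x: Tensor, weight: Tensor, bias, xp: np.ndarray,
                   pads, kh: int, kw: int):
    """Stride-1 depthwise conv via FFT; returns (out, backward closure)."""
    N, C, Hp, Wp = xp.shape
    Ho, Wo = Hp - kh + 1, Wp - kw + 1
    H, W = x.data.shape[-2:]
    pt, _, pl, _ = pads
    s = (Hp + kh - 1, Wp + kw - 1)
    w2 = weight.data[:, 0]
    Fx = sfft.rfft2(xp, s=s)
    Fw = sfft.rfft2(w2[:, ::-1, ::-1], s=s)
    full = sfft.irfft2(Fx * Fw[None], s=s)
    out = full[..., kh - 1:kh - 1 + Ho, kw - 1:kw - 1 + Wo]
    if bias is not None:
        out = out + bias.data.reshape(1, -1, 1, 1)

    def bwd(g):
        if bias is not None:
            _accum(bias, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            s2 = (Hp, Wp)  # full conv of (Ho) with (kh) is exactly Hp long
            Fg = sfft.rfft2(g, s=s2)
            Fw2 = sfft.rfft2(w2, s=s2)
            gxp = sfft.irfft2(Fg * Fw2[None], s=s2)
            _accum(x, gxp[..., pt:pt + H, pl:pl + W])
        if weight.requires_grad:
            s3 = (Hp + Ho - 1, Wp + Wo - 1)
            Fxp = sfft.rfft2(xp, s=s3)
            Fgf = sfft.rfft2(g[..., ::-1, ::-1], s=s3)
            prod = (Fxp * Fgf).sum(axis=0)
            gw_full = sfft.irfft2(prod, s=s3)
            gw = gw_full[:, Ho - 1:Ho - 1 + kh, Wo - 1:Wo - 1 + kw]
            _accum(weight, gw[:, None])

    return out, bwd


# ---------------------------------------------------------------------------
# bilinear resizing (align_corners=False convention)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=256)
def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    if n_in == n_out:
        return np.eye(n_in)
    scale = n_in / n_out
    src = np.clip((np.arange(n_out) + 0.5) * scale - 0.5, 0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = src - i0
    M = np.zeros((n_out, n_in))
    np.add.at(M, (np.arange(n_out), i0), 1.0 - w1)
    np.add.at(M, (np.arange(n_out), i1), w1)
    return M


def resize_bilinear(x, out_hw: tuple[int, int]) -> Tensor:
    """Bilinearly resize the last two axes of an NCHW tensor."""
    x = as_tensor(x)
    H, W = x.data.shape[-2:]
    Ho, Wo = out_hw
    if (H, W) == (Ho, Wo):
        return x
    Mr = _interp_matrix(H, Ho)
    Mc = _interp_matrix(W, Wo)
    out = np.matmul(np.matmul(Mr, x.data), Mc.T)

    def bwd(g):
        gx = np.matmul(np.matmul(Mr.T, g), Mc)
        _accum(x, gx)

    return _make(out, (x,), bwd)


def resize_nearest(arr: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resize for label maps (pure NumPy, no gradient)."""
    H, W = arr.shape[-2:]
    Ho, Wo = out_hw
    rows = np.minimum((np.arange(Ho) + 0.5) * H / Ho, H - 1).astype(int)
    cols = np.minimum((np.arange(Wo) + 0.5) * W / Wo, W - 1).astype(int)
    return arr[..., rows[:, None], cols[None, :]]
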