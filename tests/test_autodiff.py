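"""Finite-difference validation of the autodiff core.

Every differentiable operation the network relies on is checked against
central finite differences on small random inputs.
"""

import numpy as np
import pytest

from mmnet import autodiff as ad
from mmnet.autodiff import Tensor

RNG = np.random.default_rng(1234)


def numeric_grad(fn, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    g = np.zeros_like(x)
    flat = x.ravel()
    gf = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = fn(x)
        flat[i] = orig - eps
        fm = fn(x)
        flat[i] = orig
        gf[i] = (fp - fm) / (2 * eps)
    return g


def check_op(build, shape, tol=1e-6):
    """Compare autodiff gradient of sum(op(x)) with finite differences."""
    x0 = RNG.normal(size=shape)
    t = Tensor(x0.copy(), requires_grad=True)
    out = build(t)
    loss = ad.tsum(out)
    loss.backward()
    num = numeric_grad(lambda arr: float(build(Tensor(arr)).data.sum()), x0.copy())
    np.testing.assert_allclose(t.grad, num, atol=tol, rtol=1e-5)


@pytest.mark.parametrize("build,shape", [
    (lambda t: ad.gelu(t), (3, 4)),
    (lambda t: ad.sigmoid(t), (3, 4)),
    (lambda t: ad.relu(ad.add(t, 0.1)), (5, 5)),
    (lambda t: ad.softmax(t, axis=-1), (2, 3, 6)),
    (lambda t: ad.exp(ad.mul(t, 0.3)), (4,)),
    (lambda t: ad.log(ad.add(ad.mul(t, t), 1.0)), (4,)),
    (lambda t: ad.tmean(ad.power(t, 2.0), axis=1, keepdims=True), (3, 5)),
    (lambda t: ad.resize_bilinear(t, (7, 9)), (1, 2, 4, 5)),
    (lambda t: ad.resize_bilinear(t, (3, 3)), (1, 2, 6, 6)),
    (lambda t: ad.pad2d(t, (1, 2, 2, 1), mode="reflect"), (1, 2, 5, 5)),
    (lambda t: ad.pad2d(t, (2, 2, 1, 1), mode="constant"), (1, 2, 4, 4)),
    (lambda t: ad.concat([t, ad.mul(t, 2.0)], axis=1), (2, 3, 2, 2)),
    (lambda t: ad.transpose(t, (0, 2, 1)), (2, 3, 4)),
])
def test_elementwise_and_shape_op_gradients(build, shape):
    check_op(build, shape)


def test_matmul_gradient_both_sides():
    a0 = RNG.normal(size=(2, 3, 4))
    b0 = RNG.normal(size=(4, 5))
    a = Tensor(a0.copy(), requires_grad=True)
    b = Tensor(b0.copy(), requires_grad=True)
    ad.tsum(ad.matmul(a, b)).backward()
    num_a = numeric_grad(lambda arr: float(np.matmul(arr, b0).sum()), a0.copy())
    num_b = numeric_grad(lambda arr: float(np.matmul(a0, arr).sum()), b0.copy())
    np.testing.assert_allclose(a.grad, num_a, atol=1e-6)
    np.testing.assert_allclose(b.grad, num_b, atol=1e-6)


@pytest.mark.parametrize("stride,padding,dilation,groups,cin,cout,k", [
    (1, 1, 1, 1, 3, 4, 3),
    (2, 1, 1, 1, 3, 4, 3),
    (1, 2, 2, 1, 2, 3, 3),
    (1, (1, 2, 2, 1), 1, 4, 4, 4, 4),   # depthwise, even kernel, asymmetric pad
    (1, (3, 4, 3, 4), 1, 4, 4, 4, 8),   # depthwise, large kernel (FFT path)
    (1, 0, 1, 2, 4, 6, 1),
])
def test_conv2d_gradients(stride, padding, dilation, groups, cin, cout, k):
    x0 = RNG.normal(size=(2, cin, 7, 7))
    w0 = RNG.normal(size=(cout, cin // groups, k, k))
    b0 = RNG.normal(size=(cout,))

    def fwd(x, w, b):
        return ad.conv2d(Tensor(x), Tensor(w), Tensor(b), stride=stride,
                         padding=padding, dilation=dilation, groups=groups)

    xt = Tensor(x0.copy(), requires_grad=True)
    wt = Tensor(w0.copy(), requires_grad=True)
    bt = Tensor(b0.copy(), requires_grad=True)
    out = ad.conv2d(xt, wt, bt, stride=stride, padding=padding,
                    dilation=dilation, groups=groups)
    ad.tsum(out).backward()
    num_x = numeric_grad(lambda arr: float(fwd(arr, w0, b0).data.sum()), x0.copy())
    num_w = numeric_grad(lambda arr: float(fwd(x0, arr, b0).data.sum()), w0.copy())
    num_b = numeric_grad(lambda arr: float(fwd(x0, w0, arr).data.sum()), b0.copy())
    np.testing.assert_allclose(xt.grad, num_x, atol=1e-5)
    np.testing.assert_allclose(wt.grad, num_w, atol=1e-5)
    np.testing.assert_allclose(bt.grad, num_b, atol=1e-5)


@pytest.mark.parametrize("axes,shape,pshape", [
    ((1,), (2, 4, 3, 3), (1, 4, 1, 1)),      # channel LN on NCHW
    ((-1,), (2, 5, 6), (6,)),                 # token LN
    ((0, 2, 3), (3, 4, 3, 3), (1, 4, 1, 1)),  # batch norm statistics
])
def test_normalize_gradients(axes, shape, pshape):
    x0 = RNG.normal(size=shape)
    g0 = RNG.normal(size=pshape) + 1.0
    b0 = RNG.normal(size=pshape)

    def fwd(x, g, b):
        return ad.normalize(Tensor(x), Tensor(g), Tensor(b), axes=axes)

    xt = Tensor(x0.copy(), requires_grad=True)
    gt = Tensor(g0.copy(), requires_grad=True)
    bt = Tensor(b0.copy(), requires_grad=True)
    ad.tsum(ad.mul(ad.normalize(xt, gt, bt, axes=axes),
                   Tensor(RNG.normal(size=shape)))).backward()
    # weighted sum so the gradient is not trivially constant
    # redo with same weights for numeric comparison
    w = RNG.normal(size=shape)
    xt2 = Tensor(x0.copy(), requires_grad=True)
    gt2 = Tensor(g0.copy(), requires_grad=True)
    bt2 = Tensor(b0.copy(), requires_grad=True)
    ad.tsum(ad.mul(ad.normalize(xt2, gt2, bt2, axes=axes), Tensor(w))).backward()
    num_x = numeric_grad(lambda arr: float((fwd(arr, g0, b0).data * w).sum()), x0.copy())
    num_g = numeric_grad(lambda arr: float((fwd(x0, arr, b0).data * w).sum()), g0.copy())
    num_b = numeric_grad(lambda arr: float((fwd(x0, g0, arr).data * w).sum()), b0.copy())
    np.testing.assert_allclose(xt2.grad, num_x, atol=1e-5)
    np.testing.assert_allclose(gt2.grad, num_g, atol=1e-5)
    np.testing.assert_allclose(bt2.grad, num_b, atol=1e-5)


def test_broadcast_gradients_unbroadcast_correctly():
    a0 = RNG.normal(size=(3, 1, 4))
    b0 = RNG.normal(size=(1, 5, 4))
    a = Tensor(a0.copy(), requires_grad=True)
    b = Tensor(b0.copy(), requires_grad=True)
    ad.tsum(ad.mul(a, b)).backward()
    np.testing.assert_allclose(a.grad, np.broadcast_to(b0, (3, 5, 4)).sum(1, keepdims=True))
    np.testing.assert_allclose(b.grad, np.broadcast_to(a0, (3, 5, 4)).sum(0, keepdims=True))


def test_no_grad_suppresses_graph():
    x = Tensor(np.ones(3), requires_grad=True)
    with ad.no_grad():
        y = ad.mul(x, 2.0)
    assert not y.requires_grad and y._parents == ()


def test_clamp_gradient_masks_boundaries():
    x = Tensor(np.array([-2.0, 0.0, 2.0]), requires_grad=True)
    ad.tsum(ad.clamp(x, -1.0, 1.0)).backward()
    np.testing.assert_allclose(x.grad, [0.0, 1.0, 0.0])


def test_conv2d_channel_mismatch_raises():
    with pytest.raises(ValueError, match="channel mismatch"):
        ad.conv2d(Tensor(np.zeros((1, 3, 4, 4))), Tensor(np.zeros((2, 4, 3, 3))))
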