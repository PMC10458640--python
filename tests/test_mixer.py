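"""Mixing module: patch embedding, block equations, gating, mask head."""

import numpy as np
import pytest

from mmnet import autodiff as ad
from mmnet import nn
from mmnet.mixer import (MaskHead, MixBlock, MixerConfig, MixingModule,
                         PatchEmbed, apply_gate, channel_gate, stride8_kernel)

RNG = np.random.default_rng(11)


def _ln_channels(x, eps=1e-5):
    """Direct NumPy layer norm over the channel axis (unit gain, zero shift)."""
    mu = x.mean(axis=1, keepdims=True)
    var = x.var(axis=1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps)


def test_patch_embed_pads_then_tokenizes():
    with nn.init_rng(np.random.default_rng(0)):
        pe = PatchEmbed(64, 64, 9)
    x = ad.Tensor(RNG.normal(size=(1, 64, 352, 352)))
    with ad.no_grad():
        z = pe(x)
    # 352 -> reflect pad to 360 -> 40x40 tokens
    assert z.data.shape == (1, 64, 40, 40)


def test_patch_embed_small_grid():
    with nn.init_rng(np.random.default_rng(0)):
        pe = PatchEmbed(16, 24, 4)
    with ad.no_grad():
        z = pe(ad.Tensor(RNG.normal(size=(1, 16, 12, 12))))
    assert z.data.shape == (1, 24, 3, 3)


def test_patch_embed_degenerate_identity():
    """p=1, identity 1x1 conv, norm and activation disabled: tokens == input."""
    with nn.init_rng(np.random.default_rng(0)):
        pe = PatchEmbed(5, 5, 1, use_norm=False, use_act=False)
    pe.proj.weight.data = np.eye(5).reshape(5, 5, 1, 1)
    pe.proj.bias.data = np.zeros(5)
    x = RNG.normal(size=(2, 5, 7, 7))
    with ad.no_grad():
        z = pe(ad.Tensor(x))
    np.testing.assert_allclose(z.data, x, atol=1e-12)


def test_mix_block_preserves_token_shape():
    with nn.init_rng(np.random.default_rng(0)):
        blk = MixBlock(64, 28)
    z = ad.Tensor(RNG.normal(size=(1, 64, 40, 40)))
    with ad.no_grad():
        out = blk(z)
    assert out.data.shape == (1, 64, 40, 40)


def test_mix_block_zero_convs_reduce_to_double_layernorm():
    """With zeroed convolutions both halves pass GELU(0)=0, so the block is
    LN(LN(z)) exactly — checked against a direct two-pass computation."""
    with nn.init_rng(np.random.default_rng(0)):
        blk = MixBlock(8, 5)
    for conv in (blk.dw, blk.pw):
        conv.weight.data[...] = 0.0
        conv.bias.data[...] = 0.0
    z = RNG.normal(size=(2, 8, 6, 6))
    with ad.no_grad():
        out = blk(ad.Tensor(z))
    np.testing.assert_allclose(out.data, _ln_channels(_ln_channels(z)), atol=1e-10)


def test_block_stack_depth_and_shapes():
    cfg = MixerConfig(depth=20, dim=16, kernel_size=7, patch_size=4)
    with nn.init_rng(np.random.default_rng(0)):
        mixer = MixingModule(16, cfg)
    assert len(mixer.blocks) == 20
    z = ad.Tensor(RNG.normal(size=(1, 16, 10, 10)))
    with ad.no_grad():
        for blk in mixer.blocks:
            z = blk(z)
            assert z.data.shape == (1, 16, 10, 10)


def test_gate_of_zero_tokens_is_exactly_half():
    gate = channel_gate(ad.Tensor(np.zeros((1, 16, 5, 5))))
    np.testing.assert_array_equal(gate.data, np.full((1, 16), 0.5))


def test_gate_closed_form_for_constant_channel():
    z = np.zeros((1, 8, 4, 4))
    z[0, 3] = 10.0
    gate = channel_gate(ad.Tensor(z)).data[0]
    assert gate[3] == pytest.approx(1.0 / (1.0 + np.exp(-10)), abs=1e-9)
    others = np.delete(gate, 3)
    np.testing.assert_array_equal(others, np.full(7, 0.5))


def test_gate_always_strictly_inside_unit_interval():
    for _ in range(20):
        z = ad.Tensor(RNG.normal(size=(2, 16, 5, 5)) * 50)
        g = channel_gate(z).data
        assert np.all(g > 0.0) and np.all(g < 1.0)


def test_apply_gate_scales_each_channel():
    g = RNG.normal(size=(2, 6, 5, 5))
    gate = RNG.random((2, 6))
    out = apply_gate(ad.Tensor(g), ad.Tensor(gate)).data
    for n in range(2):
        for c in range(6):  # brute-force elementwise check
            np.testing.assert_allclose(out[n, c], gate[n, c] * g[n, c])
    np.testing.assert_array_equal(
        apply_gate(ad.Tensor(g), ad.Tensor(np.ones((2, 6)))).data, g)
    np.testing.assert_allclose(
        apply_gate(ad.Tensor(g), ad.Tensor(np.full((2, 6), 0.5))).data, 0.5 * g)


def test_apply_gate_length_mismatch_rejected():
    with pytest.raises(ValueError, match="gate length"):
        apply_gate(ad.Tensor(np.zeros((1, 6, 4, 4))), ad.Tensor(np.zeros((1, 5))))


def test_mask_head_shape_and_neutral_logits():
    with nn.init_rng(np.random.default_rng(0)):
        head = MaskHead(64)
    gated = ad.Tensor(RNG.normal(size=(1, 64, 44, 44)))
    with ad.no_grad():
        out = head(gated, (352, 352))
    assert out.data.shape == (1, 1, 352, 352)
    assert np.all((out.data >= 0) & (out.data <= 1))
    # zeroed projection -> 0.5 everywhere
    head.proj.weight.data[...] = 0.0
    head.proj.bias.data[...] = 0.0
    with ad.no_grad():
        flat = head(gated, (88, 88))
    np.testing.assert_array_equal(flat.data, np.full((1, 1, 88, 88), 0.5))


def test_mask_probability_monotone_in_logits():
    """Raising any logit never lowers the corresponding output probability."""
    logits = RNG.normal(size=(1, 1, 6, 6))
    with ad.no_grad():
        base = ad.sigmoid(ad.resize_bilinear(ad.Tensor(logits), (12, 12))).data
        bumped = logits.copy()
        bumped[0, 0, 2, 3] += 1.0
        after = ad.sigmoid(ad.resize_bilinear(ad.Tensor(bumped), (12, 12))).data
    assert np.all(after >= base - 1e-12)


def test_depth_zero_still_produces_valid_gate():
    cfg = MixerConfig(depth=0, dim=16, kernel_size=7, patch_size=4)
    with nn.init_rng(np.random.default_rng(0)):
        mixer = MixingModule(16, cfg)
    with ad.no_grad():
        gate = mixer(ad.Tensor(RNG.normal(size=(1, 16, 12, 12))), input_hw=(96, 96))
    assert gate.data.shape == (1, 16)
    assert np.all((gate.data > 0) & (gate.data < 1))


def test_layernorm_everywhere_never_batchnorm():
    cfg = MixerConfig(depth=3, dim=16, kernel_size=7, patch_size=4)
    with nn.init_rng(np.random.default_rng(0)):
        mixer = MixingModule(16, cfg)
    mods = list(mixer.modules())
    assert not any(isinstance(m, nn.BatchNorm2d) for m in mods)
    n_ln = sum(isinstance(m, nn.LayerNorm2d) for m in mods)
    assert n_ln == 2 * cfg.depth + 1  # two per block plus the patch embed


def test_channel_adapter_bridges_dim_mismatch():
    cfg = MixerConfig(depth=1, dim=8, kernel_size=3, patch_size=2)
    with pytest.raises(ValueError, match="must equal"):
        with nn.init_rng(np.random.default_rng(0)):
            MixingModule(16, cfg)
    with nn.init_rng(np.random.default_rng(0)):
        mixer = MixingModule(16, cfg, adapt_channels=True)
    with ad.no_grad():
        gate = mixer(ad.Tensor(RNG.normal(size=(1, 16, 8, 8))), input_hw=(32, 32))
    assert gate.data.shape == (1, 16)


def test_stride8_kernel_clamps_to_token_grid():
    cfg = MixerConfig(depth=2, dim=16, kernel_size=28, patch_size=9,
                      operate_resolution="stride8")
    assert stride8_kernel(cfg, (44, 44)) == 5  # ceil(44/9) = 5 tokens


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        MixerConfig(depth=-1)
    with pytest.raises(ValueError):
        MixerConfig(operate_resolution="half")
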