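"""Segmenter architecture: residual identities, ASPP, attention gates, init."""

import numpy as np
import pytest

from diagnext import nn
from diagnext.exceptions import ConfigurationError
from diagnext.nn import functional as F
from diagnext.nn.tensor import Tensor
from diagnext.segnet import (
    ASPP3D,
    AttentionGate,
    ECB,
    ECBConfig,
    SegNet,
    SegNetConfig,
    init_weights,
)

RNG = np.random.default_rng(3)
TINY = SegNetConfig(encoder_channels=(8, 16), aspp_rates=(1, 2))


def test_ecb_zero_gamma_is_identity():
    blk = ECB(ECBConfig(channels=8))
    blk.gamma.data[:] = 0.0
    x = RNG.normal(size=(1, 8, 8, 8, 4))
    out = blk(Tensor(x))
    np.testing.assert_array_equal(out.data, x)


def test_ecb_near_identity_at_init():
    blk = ECB(ECBConfig(channels=8))
    init_weights(blk, seed=123)
    x = RNG.normal(size=(1, 8, 8, 8, 4))
    out = blk(Tensor(x)).data
    # branch is scaled by 1e-6, so the block is within 1e-3 of identity
    assert np.abs(out - x).max() <= 1e-3


def test_ecb_parameter_count_oracle():
    """Enumerate every parameter of a channels=32, expansion=4 block."""
    blk = ECB(ECBConfig(channels=32, expansion=4))
    expected = (
        32 * 7 * 7 * 3 + 32  # depthwise kernel + bias
        + 32 + 32  # GroupNorm affine
        + 128 * 32 + 128  # pointwise expand
        + 32 * 128 + 32  # pointwise project
        + 32  # layer scale gamma
    )
    total = sum(p.size for _, p in blk.named_parameters())
    assert total == expected


def test_ecb_channel_mismatch():
    blk = ECB(ECBConfig(channels=8))
    with pytest.raises(ConfigurationError):
        blk(Tensor(RNG.normal(size=(1, 4, 8, 8, 4))))


def test_init_weights_reproducible_and_distributions():
    a = init_weights(SegNet(TINY), seed=123).state_dict()
    b = init_weights(SegNet(TINY), seed=123).state_dict()
    for k in a:
        np.testing.assert_array_equal(a[k], b[k])
    # layer-scale parameters all at 1e-6
    for k, v in a.items():
        if k.endswith("gamma"):
            np.testing.assert_array_equal(v, 1e-6)
    # He variance on a large depthwise kernel
    big = nn.DepthwiseConv3d(128, (7, 7, 3))
    init_weights(big, seed=123)
    fan_in = 7 * 7 * 3
    var = big.weight.data.var()
    assert abs(var - 2.0 / fan_in) / (2.0 / fan_in) < 0.10


def test_aspp_preserves_shape_and_matches_direct_oracle():
    aspp = ASPP3D(4, rates=(1, 2))
    x = RNG.normal(size=(1, 4, 8, 8, 4))
    out = aspp(Tensor(x))
    assert out.shape == x.shape
    # dilated branches agree with the brute-force convolution oracle
    from _oracles import direct_conv3d

    for branch, rate in zip(aspp.branches, aspp.rates):
        got = branch(Tensor(x)).data
        w, bias = branch.weight.data, branch.bias.data
        want = direct_conv3d(x, w, stride=1, dilation=(rate, rate, 1), pads=(rate, rate, 1)) \
            + bias.reshape(1, -1, 1, 1, 1)
        np.testing.assert_allclose(got, want, atol=1e-9)


def test_aspp_gap_branch_constant_input():
    aspp = ASPP3D(3, rates=(1,))
    x = np.full((1, 3, 4, 4, 4), 2.5)
    n, c = 1, 3
    pooled = x.mean(axis=(2, 3, 4))
    np.testing.assert_allclose(pooled, 2.5)
    out = aspp(Tensor(x))
    assert out.shape == x.shape


def test_attention_gate_hand_arithmetic():
    """Single-voxel grids with hand-set 1x1 weights."""
    gate = AttentionGate(1, 1, inter_channels=1)
    gate.wg.weight.data[:] = 2.0
    gate.wx.weight.data[:] = -1.0
    gate.wx.bias.data[:] = 0.5
    gate.psi.weight.data[:] = 3.0
    gate.psi.bias.data[:] = -0.25
    g = np.full((1, 1, 1, 1, 1), 0.7)
    x = np.full((1, 1, 1, 1, 1), 0.4)
    pre = 3.0 * max(0.0, 2.0 * 0.7 - 1.0 * 0.4 + 0.5) - 0.25
    alpha = 1.0 / (1.0 + np.exp(-pre))
    out = gate(Tensor(g), Tensor(x))
    np.testing.assert_allclose(out.data.ravel(), [alpha * 0.4], atol=1e-6)


def test_attention_gate_zero_psi_halves_skip():
    gate = AttentionGate(2, 2, inter_channels=2)
    gate.psi.weight.data[:] = 0.0
    gate.psi.bias.data[:] = 0.0
    g = RNG.normal(size=(1, 2, 4, 4, 2))
    x = RNG.normal(size=(1, 2, 4, 4, 2))
    out = gate(Tensor(g), Tensor(x))
    np.testing.assert_allclose(out.data, x / 2.0, atol=1e-12)
    att = gate.attention(Tensor(g), Tensor(x)).data
    assert ((att > 0) & (att < 1)).all()


def test_segnet_forward_shapes_and_softmax():
    net = init_weights(SegNet(TINY), 123).eval()
    img = RNG.normal(size=(2, 1, 16, 16, 8))
    out = net(img)
    assert out.probs.shape == (2, 5, 16, 16, 8)
    np.testing.assert_allclose(out.probs.sum(axis=1), 1.0, atol=1e-5)
    # batch equivariance
    flipped = net(img[::-1].copy())
    np.testing.assert_allclose(flipped.probs, out.probs[::-1], atol=1e-10)


def test_segnet_rejects_indivisible_shape():
    net = SegNet(TINY)
    with pytest.raises(ConfigurationError, match="pad_to_multiple"):
        net(RNG.normal(size=(1, 1, 15, 16, 8)))


def test_segnet_overfits_single_phantom():
    """Capacity sanity check: a tiny net memorizes one phantom to foreground
    Dice >= 0.95 within 200 gradient steps (fixed seeds)."""
    from diagnext.metrics import seg_metrics
    from diagnext.nn import AdamW, clip_grad_norm
    from diagnext.phantom import PhantomSpec, generate_phantom
    from diagnext.seg_losses import SegLossWeights, compound_seg_loss, make_boundary_maps
    from diagnext.train import prepare_volume

    spec = PhantomSpec(volume_shape=(32, 32, 8), seed=12,
                       lesion_radius_range_mm={"cyst": (3, 4.5), "tumor": (3, 4.5),
                                               "stone": (2.5, 3.5)})
    item = prepare_volume(generate_phantom(spec, "OVF", "cyst"))
    net = init_weights(SegNet(SegNetConfig(encoder_channels=(8, 16), expansion=2,
                                           aspp_rates=(1, 2))), 123).astype(np.float32)
    net.train()
    opt = AdamW(net.parameters(), lr=1e-2, weight_decay=0.0)
    x = item.seg_input[None, None]
    y = item.onehot[None]
    maps = item.boundary_maps
    weights = SegLossWeights(boundary_form="mean")  # training form
    reached = False
    for step in range(200):
        logits = net.forward_tensor(Tensor(x))
        loss, _ = compound_seg_loss(logits.softmax(axis=1), y, weights, boundary_maps=maps)
        opt.zero_grad()
        loss.backward()
        clip_grad_norm(net.parameters(), 1.0)
        opt.step()
        if step % 20 == 19:
            net.eval()
            pred = net(item.seg_input).probs[0].argmax(axis=0)
            per = seg_metrics(pred, item.mask, item.spacing)
            fg_dice = np.mean([m.dice for m in per.values()])
            net.train()
            if fg_dice >= 0.95:
                reached = True
                break
    assert reached, f"foreground Dice only {fg_dice:.3f} after 200 steps"


def test_segnet_all_parameters_receive_gradient():
    net = init_weights(SegNet(TINY), 123)
    x = Tensor(RNG.normal(size=(2, 1, 8, 8, 8)))
    logits = net.forward_tensor(x)
    (logits ** 2.0).mean().backward()
    for name, p in net.named_parameters():
        assert p.grad is not None, f"no gradient reached {name}"
        assert np.any(p.grad != 0.0) or p.size == 0, f"zero gradient at {name}"
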