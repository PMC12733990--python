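"""Compound segmentation objective: closed forms, oracles, invariants."""

import numpy as np
import pytest
from _oracles import brute_signed_distance

from diagnext.nn.tensor import Tensor
from diagnext.seg_losses import (
    SegLossWeights,
    boundary_loss,
    compound_seg_loss,
    cross_entropy,
    dice_loss,
    focal_loss,
    signed_distance_transform,
)

RNG = np.random.default_rng(21)


def _random_pair(shape=(1, 5, 4, 4, 2), seed=0):
    rng = np.random.default_rng(seed)
    logits = rng.normal(size=shape)
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs = e / e.sum(axis=1, keepdims=True)
    labels = rng.integers(0, 5, size=(shape[0],) + shape[2:])
    onehot = np.moveaxis(np.eye(5)[labels], -1, 1)
    return probs, onehot


def test_cross_entropy_closed_forms():
    probs, onehot = _random_pair()
    # perfect prediction
    assert cross_entropy(onehot, onehot).item() <= 1e-6
    # uniform prediction = ln 5
    uniform = np.full_like(onehot, 0.2)
    assert cross_entropy(uniform, onehot).item() == pytest.approx(np.log(5.0), abs=1e-4)
    # focal with exponent 0 reduces to CE
    assert focal_loss(probs, onehot, 0.0).item() == pytest.approx(
        cross_entropy(probs, onehot).item(), abs=1e-7
    )


def test_focal_hand_arithmetic_and_bounds():
    # single voxel, true-class p = 0.5, gamma = 2
    p = np.zeros((1, 5, 1, 1, 1))
    p[0, :, 0, 0, 0] = [0.5, 0.125, 0.125, 0.125, 0.125]
    y = np.zeros_like(p)
    y[0, 0] = 1.0
    val = focal_loss(p, y, 2.0).item()
    assert val == pytest.approx(0.25 * (-np.log(0.5)), abs=1e-5)
    assert val == pytest.approx(0.17329, abs=1e-5)
    # easy example fully down-weighted
    assert focal_loss(y, y, 2.0).item() == pytest.approx(0.0, abs=1e-10)
    # focal <= CE for gamma >= 0
    probs, onehot = _random_pair(seed=4)
    assert focal_loss(probs, onehot, 2.0).item() <= cross_entropy(probs, onehot).item() + 1e-12


def test_dice_loss_perfect_disjoint_and_half_overlap():
    probs, onehot = _random_pair(seed=2)
    assert dice_loss(onehot, onehot).item() <= 1e-4
    # 2x2x1 toy with half overlap in class 1
    p = np.zeros((1, 5, 2, 2, 1))
    y = np.zeros_like(p)
    p[0, 1, 0, 0, 0] = 1.0
    p[0, 1, 0, 1, 0] = 1.0
    y[0, 1, 0, 0, 0] = 1.0
    y[0, 1, 1, 0, 0] = 1.0
    p[0, 0] = 1.0 - p[0, 1:].sum(axis=0)
    y[0, 0] = 1.0 - y[0, 1:].sum(axis=0)
    # counting oracle: |A|=|B|=2, |A&B|=1 -> Dice 0.5
    inter, a, b = 1, 2, 2
    dice_c1 = 2 * inter / (a + b)
    assert dice_c1 == 0.5
    # loss = 1 - mean(0.5, 1, 1, 1) over foreground classes
    assert dice_loss(p, y).item() == pytest.approx(1.0 - np.mean([0.5, 1, 1, 1]), abs=1e-5)
    # disjoint prediction for a class -> that class Dice ~ 0
    y2 = np.roll(p, 1, axis=2)
    loss = dice_loss(p, y2).item()
    dice_class1 = 4.0 * (1.0 - loss) - 3.0  # classes 2-4 absent in both -> Dice 1
    assert dice_class1 <= 1e-3


def test_sdt_matches_brute_force_oracle():
    rng = np.random.default_rng(17)
    for _ in range(20):
        m = rng.random((8, 8, 4)) > 0.6
        if not m.any() or m.all():
            continue
        d, flag = signed_distance_transform(m)
        assert not flag
        np.testing.assert_allclose(d, brute_signed_distance(m), atol=1e-9)


def test_sdt_sign_and_adjacency():
    m = np.zeros((6, 6, 4), dtype=bool)
    m[2:4, 2:4, 1:3] = True
    d, _ = signed_distance_transform(m)
    assert ((d < 0) == m).all()
    from scipy import ndimage

    shell = ndimage.binary_dilation(m) & ~m
    assert (d[shell] > 0).all() and (d[shell] <= 1.0).all()


def test_sdt_degenerate_masks_flagged():
    d_empty, f1 = signed_distance_transform(np.zeros((4, 4, 2), dtype=bool))
    assert f1 and (d_empty > 0).all()
    d_full, f2 = signed_distance_transform(np.ones((4, 4, 2), dtype=bool))
    assert f2 and (d_full < 0).all()


def test_boundary_loss_uniform_weighting_equals_mean_d():
    y = np.zeros((1, 5, 4, 4, 2))
    y[0, 2, 1:3, 1:3, :] = 1.0
    y[0, 0] = 1.0 - y[0, 2]
    probs = np.full_like(y, 1.0 / 5)
    d, _ = signed_distance_transform(y[0, 2] > 0)
    val = boundary_loss(probs, y).item()
    assert val == pytest.approx(d.mean(), rel=1e-6)


def test_boundary_loss_1d_toy_hand_evaluation():
    """Mass on the GT voxel beats mass on a far voxel; both values match a
    hand evaluation of the distance-weighted ratio with the brute-force D."""
    y = np.zeros((1, 5, 5, 1, 1))
    y[0, 2, 2, 0, 0] = 1.0
    y[0, 0] = 1.0 - y[0, 2]
    d = brute_signed_distance(y[0, 2] > 0)

    def loss_with_mass_at(i):
        p = np.zeros_like(y)
        p[0, 2, i, 0, 0] = 1.0
        p[0, 0] = 1.0 - p[0, 2]
        return boundary_loss(p, y).item(), d[i, 0, 0]

    on_gt, d_gt = loss_with_mass_at(2)
    on_end, d_end = loss_with_mass_at(0)
    assert on_gt == pytest.approx(d_gt, abs=1e-6)
    assert on_end == pytest.approx(d_end, abs=1e-6)
    assert on_gt < on_end


def test_boundary_loss_monotone_in_displacement():
    """Translating a predicted blob away from the GT sphere never helps."""
    shape = (16, 16, 8)
    y = np.zeros((1, 5) + shape)
    zz, yy, xx = np.indices(shape)
    gt = (zz - 8) ** 2 + (yy - 8) ** 2 + (xx - 4) ** 2 <= 9
    y[0, 2][gt] = 1.0
    y[0, 0] = 1.0 - y[0, 2]
    losses = []
    for shift in range(0, 5):
        blob = np.roll(gt, shift, axis=0)
        p = np.zeros_like(y)
        p[0, 2][blob] = 1.0
        p[0, 0] = 1.0 - p[0, 2]
        losses.append(boundary_loss(p, y).item())
    assert all(a <= b + 1e-9 for a, b in zip(losses, losses[1:]))


def test_compound_recombination_and_reductions():
    probs, onehot = _random_pair(seed=9)
    w = SegLossWeights()
    total, breakdown = compound_seg_loss(probs, onehot, w)
    recombined = (
        0.4 * breakdown["ce"] + 0.3 * breakdown["dice"]
        + 0.2 * breakdown["boundary"] + 0.1 * breakdown["focal"]
    )
    assert total.item() == pytest.approx(recombined, abs=1e-7)
    # single-term and null reductions
    only_ce, _ = compound_seg_loss(probs, onehot, SegLossWeights(1, 0, 0, 0))
    assert only_ce.item() == pytest.approx(cross_entropy(probs, onehot).item(), abs=1e-10)
    zero, _ = compound_seg_loss(probs, onehot, SegLossWeights(0, 0, 0, 0))
    assert zero.item() == 0.0
    with pytest.raises(Exception):
        SegLossWeights(alpha=-0.1)


def test_losses_differentiable():
    probs, onehot = _random_pair(seed=12)
    logits = Tensor(np.log(probs), requires_grad=True)
    p = logits.softmax(axis=1)
    total, _ = compound_seg_loss(p, onehot)
    total.backward()
    assert logits.grad is not None and np.isfinite(logits.grad).all()
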