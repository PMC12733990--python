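"""Finite-difference gradient checks and shape algebra for the NN core."""

import numpy as np
import pytest

from diagnext import nn
from diagnext.nn import functional as F
from diagnext.nn.tensor import Tensor


def numeric_grad(fn, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar ``fn`` w.r.t. array ``x``."""
    g = np.zeros_like(x, dtype=float)
    flat = x.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = fn(x)
        flat[i] = orig - eps
        lo = fn(x)
        flat[i] = orig
        gf[i] = (hi - lo) / (2 * eps)
    return g


def check_grad(make_loss, x: np.ndarray, tol: float = 1e-5):
    t = Tensor(x.copy(), requires_grad=True)
    loss = make_loss(t)
    loss.backward()
    num = numeric_grad(lambda arr: make_loss(Tensor(arr)).item(), x.copy())
    np.testing.assert_allclose(t.grad, num, rtol=tol, atol=tol)


RNG = np.random.default_rng(7)
_W_FIXED = np.random.default_rng(11).normal(size=(3, 4))


@pytest.mark.parametrize(
    "op",
    [
        lambda t: (t * t + 3.0 * t).sum(),
        lambda t: (t.exp() + (t * t + 1.0).log()).mean(),
        lambda t: t.sigmoid().sum(),
        lambda t: t.gelu().sum(),
        lambda t: t.silu().sum(),
        lambda t: t.softplus().sum(),
        lambda t: t.tanh().mean(),
        lambda t: (t.softmax(axis=-1) * Tensor(_W_FIXED)).sum(),
        lambda t: (t.log_softmax(axis=-1) * Tensor(_W_FIXED)).sum(),
        lambda t: t.clip(-0.5, 0.5).sum(),
        lambda t: (t.reshape(12) ** 3.0).sum(),
        lambda t: t.mean(axis=0).sum(),
        lambda t: (t[1:, :2] * 2.0).sum(),
    ],
)
def test_elementwise_and_reduction_grads(op):
    check_grad(op, RNG.normal(size=(3, 4)))


def test_digamma_gammaln_grads():
    x = RNG.uniform(1.0, 5.0, size=(6,))
    check_grad(lambda t: t.digamma().sum(), x, tol=1e-4)
    check_grad(lambda t: t.gammaln().sum(), x, tol=1e-4)


def test_matmul_and_broadcast_grads():
    a = RNG.normal(size=(3, 4))
    b = RNG.normal(size=(4, 2))
    ta = Tensor(a, requires_grad=True)
    tb = Tensor(b, requires_grad=True)
    ((ta @ tb) ** 2.0).sum().backward()
    num_a = numeric_grad(lambda arr: float(((arr @ b) ** 2).sum()), a.copy())
    num_b = numeric_grad(lambda arr: float(((a @ arr) ** 2).sum()), b.copy())
    np.testing.assert_allclose(ta.grad, num_a, atol=1e-5)
    np.testing.assert_allclose(tb.grad, num_b, atol=1e-5)
    # broadcasting: (3,4) + (4,)
    bias = Tensor(RNG.normal(size=4), requires_grad=True)
    (Tensor(a) + bias).sum().backward()
    np.testing.assert_allclose(bias.grad, np.full(4, 3.0))


def test_concatenate_grad():
    a, b = RNG.normal(size=(2, 3)), RNG.normal(size=(2, 2))
    ta = Tensor(a, requires_grad=True)
    tb = Tensor(b, requires_grad=True)
    (nn.concatenate([ta, tb], axis=1) ** 2.0).sum().backward()
    np.testing.assert_allclose(ta.grad, 2 * a)
    np.testing.assert_allclose(tb.grad, 2 * b)


def test_reused_node_accumulates_gradient():
    x = Tensor(np.array([2.0]), requires_grad=True)
    y = x * x + x  # dy/dx = 2x + 1 = 5
    y.sum().backward()
    np.testing.assert_allclose(x.grad, [5.0])


# ----------------------------------------------------------------------
# convolution primitives
# ----------------------------------------------------------------------

from _oracles import direct_conv3d as _direct_conv3d


@pytest.mark.parametrize("stride,dilation,pads", [(1, 1, (1, 1, 1)), (2, 1, (0, 0, 0)), (1, 2, (2, 2, 2))])
def test_conv3d_matches_direct_oracle(stride, dilation, pads):
    x = RNG.normal(size=(2, 3, 6, 5, 4))
    w = RNG.normal(size=(4, 3, 3, 3, 3)) if stride == 1 else RNG.normal(size=(4, 3, 2, 2, 2))
    got = F.conv3d(Tensor(x), Tensor(w), stride=stride, dilation=dilation, padding=pads)
    want = _direct_conv3d(x, w, stride=stride, dilation=dilation, pads=pads)
    np.testing.assert_allclose(got.data, want, atol=1e-10)


def test_conv3d_rejects_undersized_spatial():
    x = Tensor(RNG.normal(size=(1, 2, 4, 4, 2)))
    w = Tensor(RNG.normal(size=(2, 2, 3, 3, 3)))
    with pytest.raises(ValueError, match="smaller than"):
        F.conv3d(x, w, dilation=6, padding=(6, 6, 0))


def test_conv3d_grads():
    x = RNG.normal(size=(1, 2, 4, 4, 3))
    w = RNG.normal(size=(2, 2, 3, 3, 3))
    b = RNG.normal(size=2)
    tw, tb = Tensor(w, requires_grad=True), Tensor(b, requires_grad=True)

    def run(xt):
        return (F.conv3d(xt, tw, tb, padding="same") ** 2.0).sum()

    tx = Tensor(x.copy(), requires_grad=True)
    run(tx).backward()
    num_x = numeric_grad(lambda a: (F.conv3d(Tensor(a), Tensor(w), Tensor(b), padding="same").data ** 2).sum(), x.copy())
    num_w = numeric_grad(lambda a: (F.conv3d(Tensor(x), Tensor(a), Tensor(b), padding="same").data ** 2).sum(), w.copy())
    num_b = numeric_grad(lambda a: (F.conv3d(Tensor(x), Tensor(w), Tensor(a), padding="same").data ** 2).sum(), b.copy())
    np.testing.assert_allclose(tx.grad, num_x, atol=1e-4)
    np.testing.assert_allclose(tw.grad, num_w, atol=1e-4)
    np.testing.assert_allclose(tb.grad, num_b, atol=1e-4)


def test_depthwise_fft_matches_shift_conv():
    """FFT depthwise path agrees with the dense conv on a block-diagonal kernel."""
    x = RNG.normal(size=(2, 3, 8, 7, 5))
    w = RNG.normal(size=(3, 5, 5, 3))
    got = F.depthwise_conv3d(Tensor(x), Tensor(w))
    wd = np.zeros((3, 3, 5, 5, 3))
    for c in range(3):
        wd[c, c] = w[c]
    want = F.conv3d(Tensor(x), Tensor(wd), padding="same")
    np.testing.assert_allclose(got.data, want.data, atol=1e-9)


def test_depthwise_grads():
    x = RNG.normal(size=(1, 2, 5, 4, 3))
    w = RNG.normal(size=(2, 3, 3, 3))
    b = RNG.normal(size=2)
    tx = Tensor(x.copy(), requires_grad=True)
    tw = Tensor(w, requires_grad=True)
    tb = Tensor(b, requires_grad=True)
    (F.depthwise_conv3d(tx, tw, tb) ** 2.0).sum().backward()
    num_x = numeric_grad(lambda a: (F.depthwise_conv3d(Tensor(a), Tensor(w), Tensor(b)).data ** 2).sum(), x.copy())
    num_w = numeric_grad(lambda a: (F.depthwise_conv3d(Tensor(x), Tensor(a), Tensor(b)).data ** 2).sum(), w.copy())
    num_b = numeric_grad(lambda a: (F.depthwise_conv3d(Tensor(x), Tensor(w), Tensor(a)).data ** 2).sum(), b.copy())
    np.testing.assert_allclose(tx.grad, num_x, atol=1e-4)
    np.testing.assert_allclose(tw.grad, num_w, atol=1e-4)
    np.testing.assert_allclose(tb.grad, num_b, atol=1e-4)


def test_pointwise_grads():
    x = RNG.normal(size=(2, 3, 2, 2, 2))
    w = RNG.normal(size=(4, 3))
    tx = Tensor(x.copy(), requires_grad=True)
    tw = Tensor(w, requires_grad=True)
    (F.pointwise_conv3d(tx, tw) ** 2.0).sum().backward()
    num_x = numeric_grad(lambda a: (F.pointwise_conv3d(Tensor(a), Tensor(w)).data ** 2).sum(), x.copy())
    num_w = numeric_grad(lambda a: (F.pointwise_conv3d(Tensor(x), Tensor(a)).data ** 2).sum(), w.copy())
    np.testing.assert_allclose(tx.grad, num_x, atol=1e-5)
    np.testing.assert_allclose(tw.grad, num_w, atol=1e-5)


def test_linear_resize_constants_and_grad():
    x = np.full((1, 1, 4, 4, 4), 3.14)
    out = F.linear_resize3d(Tensor(x), (6, 3, 8))
    assert out.shape == (1, 1, 6, 3, 8)
    np.testing.assert_allclose(out.data, 3.14)
    xr = RNG.normal(size=(1, 2, 4, 3, 2))
    tx = Tensor(xr.copy(), requires_grad=True)
    (F.linear_resize3d(tx, (6, 5, 3)) ** 2.0).sum().backward()
    num = numeric_grad(lambda a: (F.linear_resize3d(Tensor(a), (6, 5, 3)).data ** 2).sum(), xr.copy())
    np.testing.assert_allclose(tx.grad, num, atol=1e-5)


# ----------------------------------------------------------------------
# layers
# ----------------------------------------------------------------------

def test_groupnorm_normalizes_per_group():
    gn = nn.GroupNorm(8, groups=4)
    x = RNG.normal(size=(2, 8, 3, 3, 2)) * 5 + 2
    y = gn(Tensor(x)).data
    yg = y.reshape(2, 4, -1)
    np.testing.assert_allclose(yg.mean(axis=2), 0.0, atol=1e-7)
    np.testing.assert_allclose(yg.std(axis=2), 1.0, atol=1e-3)


def test_groupnorm_grad():
    gn = nn.GroupNorm(4, groups=2)
    x = RNG.normal(size=(1, 4, 2, 2, 2))

    def run(arr):
        return (gn(Tensor(arr)) ** 2.0).sum()

    tx = Tensor(x.copy(), requires_grad=True)
    (gn(tx) ** 2.0).sum().backward()
    num = numeric_grad(lambda a: run(a).item(), x.copy())
    np.testing.assert_allclose(tx.grad, num, atol=1e-4)


def test_se3d_symmetric_channels_get_equal_gates():
    """Identical channel statistics must produce identical SE gates."""
    se = nn.SE3D(4, reduction=2)
    # tie the excitation weights so the channel-permutation symmetry is exact
    se.fc1.weight.data[:] = 0.1
    se.fc2.weight.data[:] = 0.2
    x = np.tile(RNG.normal(size=(1, 1, 3, 3, 2)), (1, 4, 1, 1, 1))
    gates = se.gates(Tensor(x)).data
    assert np.ptp(gates) < 1e-12
    # hand computation of the squeeze-excite chain
    z = x.mean(axis=(2, 3, 4))
    h = np.maximum(z @ se.fc1.weight.data + se.fc1.bias.data, 0)
    want = 1 / (1 + np.exp(-(h @ se.fc2.weight.data + se.fc2.bias.data)))
    np.testing.assert_allclose(gates, want, atol=1e-12)


def test_dropout_eval_is_identity_and_train_scales():
    d = nn.Dropout(0.5)
    x = Tensor(np.ones((1, 2, 4, 4, 4)))
    d.eval()
    np.testing.assert_array_equal(d(x).data, x.data)
    d.train()
    d.seed(0)
    y = d(x).data
    assert set(np.unique(y)) <= {0.0, 2.0}


def test_adamw_minimizes_quadratic():
    p = nn.Parameter(np.array([5.0, -3.0]))
    opt = nn.AdamW([p], lr=0.2, weight_decay=0.0)
    for _ in range(200):
        opt.zero_grad()
        ((p * p).sum()).backward()
        opt.step()
    np.testing.assert_allclose(p.data, 0.0, atol=1e-2)


def test_clip_grad_norm():
    p = nn.Parameter(np.zeros(4))
    p.grad = np.full(4, 10.0)
    pre = nn.clip_grad_norm([p], 1.0)
    assert pre == pytest.approx(20.0)
    assert np.linalg.norm(p.grad) == pytest.approx(1.0, rel=1e-6)


def test_state_dict_roundtrip():
    lin = nn.Linear(3, 2)
    state = lin.state_dict()
    lin2 = nn.Linear(3, 2)
    lin2.load_state_dict(state)
    np.testing.assert_array_equal(lin2.weight.data, lin.weight.data)
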