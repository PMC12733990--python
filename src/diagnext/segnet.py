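"""Attention-gated 3D encoder-decoder segmenter with ConvNeXt-style blocks.

Encoder levels stack Enhanced Convolutional Blocks (ECB): a large-kernel
(7x7x3) depthwise convolution, GroupNorm, an inverted pointwise bottleneck
with GELU, and a residual scaled by a per-channel LayerScale parameter
initialized near zero.  The bottleneck applies 3D atrous spatial pyramid
pooling (parallel dilated convolutions plus a pooled branch); decoder skip
connections pass through additive spatial attention gates.  Output is a
per-voxel softmax over 5 classes (background, kidney, cyst, tumor, stone).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .exceptions import ConfigurationError
from .nn import functional as F
from .nn.tensor import Tensor

__all__ = ["ECBConfig", "SegNetConfig", "SegOutput", "ECB", "ASPP3D", "AttentionGate",
           "SegNet", "init_weights"]

N_CLASSES = 5


@dataclass(frozen=True)
class ECBConfig:
    channels: int
    dw_kernel: tuple[int, int, int] = (7, 7, 3)
    expansion: int = 4
    layerscale_init: float = 1e-6

    def __post_init__(self):
        if self.channels < 1 or self.expansion < 1:
            raise ConfigurationError("channels and expansion must be >= 1")


@dataclass(frozen=True)
class SegNetConfig:
    encoder_channels: tuple[int, ...] = (32, 64, 128, 256)
    n_classes: int = N_CLASSES
    aspp_rates: tuple[int, ...] = (1, 3, 6)
    dropout_rate: float = 0.1
    dw_kernel: tuple[int, int, int] = (7, 7, 3)
    expansion: int = 4
    # patchify stem: > 1 trades full-resolution block work for a strided
    # entry convolution plus a matching trilinear upsample before the head
    stem_stride: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self):
        if len(self.encoder_channels) < 2:
            raise ConfigurationError("need at least 2 encoder levels")
        if self.n_classes != N_CLASSES:
            raise ConfigurationError("segmenter is defined for 5 classes")

    @property
    def levels(self) -> int:
        return len(self.encoder_channels)


@dataclass
class SegOutput:
    probs: np.ndarray  # (N, 5, D, H, W), voxel softmax
    logits: np.ndarray

    def __post_init__(self):
        s = self.probs.sum(axis=1)
        if not np.allclose(s, 1.0, atol=1e-5):
            raise ValueError("per-voxel probabilities must sum to 1")


class ECB(nn.Module):
    """Enhanced Convolutional Block: x + gamma * PW(GELU(PW(GN(DW(x)))))."""

    def __init__(self, cfg: ECBConfig):
        super().__init__()
        c = cfg.channels
        self.cfg = cfg
        self.dw = nn.DepthwiseConv3d(c, cfg.dw_kernel)
        self.norm = nn.GroupNorm(c)
        self.pw_expand = nn.PointwiseConv3d(c, c * cfg.expansion)
        self.pw_project = nn.PointwiseConv3d(c * cfg.expansion, c)
        self.gamma = nn.Parameter(np.full(c, cfg.layerscale_init))

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.channels:
            raise ConfigurationError(
                f"ECB expects {self.cfg.channels} channels, got {x.shape[1]}"
            )
        h = self.dw(x)
        h = self.norm(h)
        h = self.pw_expand(h)
        h = h.gelu()
        h = self.pw_project(h)
        return x + h * self.gamma.reshape(1, -1, 1, 1, 1)


class ASPP3D(nn.Module):
    """Atrous spatial pyramid pooling: pooled branch + dilated 3x3x3 branches.

    Dilation is applied in-plane only (through-plane dilation 1) so shallow
    bottleneck stacks remain valid; the per-axis span precondition is
    enforced by the convolution itself.
    """

    def __init__(self, channels: int, rates=(1, 3, 6)):
        super().__init__()
        self.rates = tuple(rates)
        self.branches = nn.ModuleList(
            [nn.Conv3d(channels, channels, 3, dilation=(r, r, 1), padding="same")
             for r in self.rates]
        )
        self.pool_proj = nn.PointwiseConv3d(channels, channels)
        self.fuse = nn.PointwiseConv3d(channels * (len(self.rates) + 1), channels)

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[:2]
        pooled = F.global_avg_pool(x).reshape(n, c, 1, 1, 1)
        gap = self.pool_proj(pooled * Tensor(np.ones((1, 1) + x.shape[2:], dtype=x.data.dtype)))
        outs = [gap] + [b(x) for b in self.branches]
        return self.fuse(nn.concatenate(outs, axis=1))


class AttentionGate(nn.Module):
    """Additive spatial attention: alpha = sigmoid(psi(ReLU(Wg g + Wx x + b)))."""

    def __init__(self, gate_channels: int, skip_channels: int, inter_channels: int | None = None):
        super().__init__()
        inter = inter_channels or max(1, skip_channels // 2)
        self.wg = nn.PointwiseConv3d(gate_channels, inter, bias=False)
        self.wx = nn.PointwiseConv3d(skip_channels, inter, bias=True)
        self.psi = nn.PointwiseConv3d(inter, 1, bias=True)

    def attention(self, g: Tensor, x: Tensor) -> Tensor:
        if g.shape[2:] != x.shape[2:]:
            raise ConfigurationError("gating signal and skip features must be spatially aligned")
        return self.psi((self.wg(g) + self.wx(x)).relu()).sigmoid()

    def forward(self, g: Tensor, x: Tensor) -> Tensor:
        return x * self.attention(g, x)


class _Down(nn.Module):
    def __init__(self, cin, cout):
        super().__init__()
        self.conv = nn.Conv3d(cin, cout, 2, stride=2, padding=(0, 0, 0))

    def forward(self, x):
        return self.conv(x)


class _Up(nn.Module):
    """Trilinear x2 upsampling followed by channel projection."""

    def __init__(self, cin, cout):
        super().__init__()
        self.proj = nn.PointwiseConv3d(cin, cout)

    def forward(self, x):
        out_shape = tuple(2 * s for s in x.shape[2:])
        return self.proj(F.linear_resize3d(x, out_shape))


class SegNet(nn.Module):
    """DiagNeXt-Seg: U-shaped segmenter over 5 tissue classes."""

    def __init__(self, cfg: SegNetConfig = SegNetConfig()):
        super().__init__()
        self.cfg = cfg
        chans = cfg.encoder_channels
        ecb = lambda c: ECB(ECBConfig(c, cfg.dw_kernel, cfg.expansion))
        if cfg.stem_stride == (1, 1, 1):
            self.stem = nn.PointwiseConv3d(1, chans[0])
        else:
            self.stem = nn.Conv3d(1, chans[0], 3, stride=cfg.stem_stride, padding=(1, 1, 1))
        self.enc = nn.ModuleList([ecb(c) for c in chans])
        self.down = nn.ModuleList([_Down(chans[i], chans[i + 1]) for i in range(len(chans) - 1)])
        self.aspp = ASPP3D(chans[-1], cfg.aspp_rates)
        self.up = nn.ModuleList(
            [_Up(chans[i + 1], chans[i]) for i in reversed(range(len(chans) - 1))]
        )
        self.gates = nn.ModuleList(
            [AttentionGate(chans[i], chans[i]) for i in reversed(range(len(chans) - 1))]
        )
        self.dec_fuse = nn.ModuleList(
            [nn.PointwiseConv3d(2 * chans[i], chans[i]) for i in reversed(range(len(chans) - 1))]
        )
        self.dec = nn.ModuleList([ecb(chans[i]) for i in reversed(range(len(chans) - 1))])
        self.dropout = nn.Dropout(cfg.dropout_rate)
        self.head = nn.PointwiseConv3d(chans[0], cfg.n_classes)

    def _check_shape(self, spatial):
        div = 2 ** (self.cfg.levels - 1)
        divs = tuple(div * s for s in self.cfg.stem_stride)
        if any(s % d for s, d in zip(spatial, divs)):
            raise ConfigurationError(
                f"spatial dims {spatial} must be divisible by {divs}; apply pad_to_multiple first"
            )

    def forward_tensor(self, x: Tensor) -> Tensor:
        """Logits tensor (tracked) for training."""
        self._check_shape(x.shape[2:])
        full_shape = x.shape[2:]
        skips = []
        h = self.stem(x)
        for i, block in enumerate(self.enc):
            h = block(h)
            if i < len(self.down):
                skips.append(h)
                h = self.down[i](h)
        h = self.aspp(h)
        for up, gate, fuse, block, skip in zip(self.up, self.gates, self.dec_fuse, self.dec,
                                               reversed(skips)):
            h = up(h)
            gated = gate(h, skip)
            h = fuse(nn.concatenate([h, gated], axis=1))
            h = block(h)
        h = self.dropout(h)
        if self.cfg.stem_stride != (1, 1, 1):
            h = F.linear_resize3d(h, full_shape)
        return self.head(h)

    def forward(self, image: np.ndarray) -> SegOutput:
        """Inference on a (N, 1, D, H, W) or (D, H, W) array; deterministic in eval mode."""
        arr = np.asarray(image)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float64)
        if arr.ndim == 3:
            arr = arr[None, None]
        logits = self.forward_tensor(Tensor(arr))
        probs = logits.softmax(axis=1)
        return SegOutput(probs=probs.data, logits=logits.data)


def init_weights(net: nn.Module, seed: int = 123) -> nn.Module:
    """He-normal depthwise kernels, Xavier-uniform pointwise/dense kernels,
    LayerScale parameters at 1e-6, zero biases, unit norm gains."""
    rng = np.random.default_rng(seed)
    for name, p in net.named_parameters():
        leaf = name.rsplit(".", 1)[-1]
        if leaf == "gamma":
            p.data = np.full(p.data.shape, 1e-6)
        elif leaf == "bias" or name.endswith("norm.bias"):
            p.data = np.zeros_like(p.data)
        elif ".norm." in name or name.endswith("norm.weight"):
            p.data = np.ones_like(p.data) if leaf == "weight" else np.zeros_like(p.data)
        elif leaf == "weight" and p.data.ndim == 4:  # depthwise (C, kd, kh, kw)
            fan_in = int(np.prod(p.data.shape[1:]))
            p.data = rng.normal(0.0, np.sqrt(2.0 / fan_in), p.data.shape)
        elif leaf == "weight" and p.data.ndim == 5:  # dense conv
            fan_in = int(np.prod(p.data.shape[1:]))
            fan_out = p.data.shape[0] * int(np.prod(p.data.shape[2:]))
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            p.data = rng.uniform(-lim, lim, p.data.shape)
        elif leaf == "weight" and p.data.ndim == 2:
            # pointwise / linear: Xavier uniform (symmetric in fan_in + fan_out)
            lim = np.sqrt(6.0 / sum(p.data.shape))
            p.data = rng.uniform(-lim, lim, p.data.shape)
        elif leaf in {"alpha", "block_scale"}:
            p.data = np.full(p.data.shape, 0.1)
    return net
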