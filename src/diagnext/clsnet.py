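"""Multi-resolution evidential classifier for lesion ROI patches.

Three parallel pathways process the 96x96x32 ROI at full, 0.75x and 0.5x
resolution with scale-matched kernels (small kernels / wide channels at
fine scale, large kernels / narrow channels at coarse scale).  Pathway
features pass through Adaptive Convolutional Blocks (GroupNorm -> 5x5x3
depthwise -> SiLU -> inverted pointwise bottleneck with dropout ->
squeeze-excite gating -> residual scaled by alpha * LayerScale).  A
context-aware fusion module weighs the pathways with a softmax attention
conditioned on pooled context and the segmentation confidence S, the
fused descriptor is confidence-modulated (floor kappa), and an
evidential head emits Dirichlet concentrations over the four pathology
classes (normal, cyst, tumor, stone): alpha = softplus(z) + 1, expected
probabilities alpha/S_alpha and uncertainty u = K / S_alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .exceptions import ConfigurationError
from .nn import functional as F
from .nn.tensor import Tensor, as_tensor

__all__ = [
    "ACBConfig",
    "HMRPConfig",
    "PathwayConfig",
    "ClsNetConfig",
    "DirichletPrediction",
    "ACB",
    "Pathway",
    "CAFF",
    "ClsNet",
    "hmrp_streams",
    "cmfs_scale",
]

K_CLASSES = 4
CLS_CLASSES = ("normal", "cyst", "tumor", "stone")
ROI_SHAPE = (96, 96, 32)


@dataclass(frozen=True)
class ACBConfig:
    channels: int
    dw_kernel: tuple[int, int, int] = (5, 5, 3)
    dropout: float = 0.15
    block_scale_init: float = 0.1
    se_reduction: int = 4
    expansion: int = 4

    def __post_init__(self):
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must be in [0, 1)")
        if self.channels < self.se_reduction:
            raise ConfigurationError("channels must be >= se_reduction")


@dataclass(frozen=True)
class PathwayConfig:
    name: str
    input_shape: tuple[int, int, int]
    kernel: tuple[int, int, int]
    channels: tuple[int, ...]
    stem_stride: tuple[int, int, int] = (2, 2, 2)
    dropout: float = 0.15


@dataclass(frozen=True)
class HMRPConfig:
    fine: PathwayConfig = field(default_factory=lambda: PathwayConfig(
        "fine", (96, 96, 32), (3, 3, 3), (256, 512, 1024)))
    medium: PathwayConfig = field(default_factory=lambda: PathwayConfig(
        "medium", (72, 72, 24), (5, 5, 3), (128, 256, 512)))
    coarse: PathwayConfig = field(default_factory=lambda: PathwayConfig(
        "coarse", (48, 48, 16), (7, 7, 5), (64, 128, 256)))

    def __post_init__(self):
        f = np.array(self.fine.input_shape)
        if tuple((0.75 * f).astype(int)) != self.medium.input_shape:
            raise ConfigurationError("medium stream must be 0.75x the fine stream")
        if tuple((0.5 * f).astype(int)) != self.coarse.input_shape:
            raise ConfigurationError("coarse stream must be 0.5x the fine stream")

    @property
    def streams(self):
        return (self.fine, self.medium, self.coarse)


def _tiny_pathways() -> HMRPConfig:
    """Desk-scale schedule: the printed channel ranges divided by 16."""
    return HMRPConfig(
        fine=PathwayConfig("fine", (96, 96, 32), (3, 3, 3), (16, 32, 64), (4, 4, 2), dropout=0.05),
        medium=PathwayConfig("medium", (72, 72, 24), (5, 5, 3), (8, 16, 32), (3, 3, 2), dropout=0.05),
        coarse=PathwayConfig("coarse", (48, 48, 16), (7, 7, 5), (4, 8, 16), (2, 2, 1), dropout=0.05),
    )


@dataclass(frozen=True)
class ClsNetConfig:
    hmrp: HMRPConfig = field(default_factory=HMRPConfig)
    fused_width: int = 512
    attn_hidden: int = 32
    kappa: float = 0.5
    dropout: float = 0.15

    @staticmethod
    def tiny(fused_width: int = 64, attn_hidden: int = 16) -> "ClsNetConfig":
        return ClsNetConfig(hmrp=_tiny_pathways(), fused_width=fused_width,
                            attn_hidden=attn_hidden, dropout=0.05)


@dataclass
class DirichletPrediction:
    """Dirichlet concentrations over (normal, cyst, tumor, stone)."""

    alpha: np.ndarray  # (K,)

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.shape != (K_CLASSES,) or (self.alpha < 1.0 - 1e-9).any():
            raise ValueError("alpha must be K=4 concentrations, each >= 1")

    @property
    def strength_S(self) -> float:
        return float(self.alpha.sum())

    @property
    def expected_probs(self) -> np.ndarray:
        return self.alpha / self.strength_S

    @property
    def uncertainty_u(self) -> float:
        return K_CLASSES / self.strength_S

    @property
    def predicted_class(self) -> str:
        return CLS_CLASSES[int(self.alpha.argmax())]


class ACB(nn.Module):
    """Adaptive Convolutional Block (see module docstring for the chain)."""

    def __init__(self, cfg: ACBConfig):
        super().__init__()
        c = cfg.channels
        self.cfg = cfg
        self.norm = nn.GroupNorm(c, groups=min(4, c))
        self.dw = nn.DepthwiseConv3d(c, cfg.dw_kernel)
        self.pw_expand = nn.PointwiseConv3d(c, c * cfg.expansion)
        self.drop = nn.Dropout(cfg.dropout)
        self.pw_project = nn.PointwiseConv3d(c * cfg.expansion, c)
        self.se = nn.SE3D(c, cfg.se_reduction)
        self.alpha = nn.Parameter(np.array(cfg.block_scale_init))
        self.layerscale = nn.Parameter(np.ones(c))

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.channels:
            raise ConfigurationError(
                f"ACB expects {self.cfg.channels} channels, got {x.shape[1]}"
            )
        h = self.dw(self.norm(x))
        h = self.pw_expand(h.silu())
        h = self.pw_project(self.drop(h))
        h = self.se(h)
        scale = self.alpha.reshape(1, 1, 1, 1, 1) * self.layerscale.reshape(1, -1, 1, 1, 1)
        return x + h * scale


def hmrp_streams(patch: np.ndarray, cfg: HMRPConfig = HMRPConfig()):
    """Fine / medium / coarse views of a batch of ROI patches.

    Accepts (96, 96, 32) or (N, 96, 96, 32); returns three arrays with a
    leading batch axis, trilinearly downsampled for medium and coarse.
    """
    arr = np.asarray(patch)
    if arr.dtype not in (np.float32, np.float64):
        arr = arr.astype(np.float64)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.shape[1:] != cfg.fine.input_shape:
        raise ValueError(f"expected ROI shape {cfg.fine.input_shape}, got {arr.shape[1:]}")
    x = arr[:, None]  # (N, 1, D, H, W)
    fine = x
    medium = F.linear_resize3d(Tensor(x), cfg.medium.input_shape).data
    coarse = F.linear_resize3d(Tensor(x), cfg.coarse.input_shape).data
    return fine, medium, coarse


class Pathway(nn.Module):
    """Strided stem, one ACB per stage with 2x downsampling between stages,
    global average pooling into a descriptor of the top stage width."""

    def __init__(self, cfg: PathwayConfig):
        super().__init__()
        self.cfg = cfg
        chans = cfg.channels
        self.stem = nn.Conv3d(1, chans[0], 3, stride=cfg.stem_stride, padding=(1, 1, 1))
        self.blocks = nn.ModuleList(
            [ACB(ACBConfig(c, cfg.kernel, dropout=cfg.dropout)) for c in chans]
        )
        self.downs = nn.ModuleList(
            [nn.Conv3d(chans[i], chans[i + 1], 2, stride=2, padding=(0, 0, 0))
             for i in range(len(chans) - 1)]
        )

    @property
    def out_width(self) -> int:
        return self.cfg.channels[-1]

    def forward(self, x) -> tuple[Tensor, Tensor]:
        """Returns (descriptor (N, C_top), top feature map)."""
        x = as_tensor(x)
        if tuple(x.shape[2:]) != self.cfg.input_shape:
            raise ConfigurationError(
                f"{self.cfg.name} pathway expects {self.cfg.input_shape}, got {x.shape[2:]}"
            )
        h = self.stem(x)
        for i, block in enumerate(self.blocks):
            h = block(h)
            if i < len(self.downs):
                h = self.downs[i](h)
        return F.global_avg_pool(h), h


class CAFF(nn.Module):
    """Context-aware fusion: per-stream spatial attention + pooling +
    projection to a common width; stream weights w_s = softmax over a
    two-layer transform of (pooled context, segmentation confidence S)."""

    def __init__(self, stream_widths, fused_width: int = 512, hidden: int = 32):
        super().__init__()
        self.spatial_att = nn.ModuleList(
            [nn.PointwiseConv3d(w, 1) for w in stream_widths]
        )
        self.proj = nn.ModuleList(
            [nn.Linear(w, fused_width) for w in stream_widths]
        )
        self.att_fc1 = nn.Linear(sum(stream_widths) + 1, hidden)
        self.att_fc2 = nn.Linear(hidden, len(stream_widths))

    def stream_weights(self, pooled: list[Tensor], confidence_S: Tensor) -> Tensor:
        ctx = nn.concatenate(pooled + [confidence_S.reshape(-1, 1)], axis=1)
        logits = self.att_fc2(self.att_fc1(ctx).relu())
        return logits.softmax(axis=1)

    def forward(self, feature_maps: list[Tensor], confidence_S: Tensor) -> tuple[Tensor, Tensor]:
        if len(feature_maps) != len(self.proj):
            raise ConfigurationError(f"expected {len(self.proj)} streams")
        pooled = []
        projected = []
        for fmap, att, proj in zip(feature_maps, self.spatial_att, self.proj):
            a = att(fmap).sigmoid()  # (N, 1, d, h, w) spatial attention
            attended = fmap * a
            p = F.global_avg_pool(attended)
            pooled.append(p)
            projected.append(proj(p))
        ws = self.stream_weights(pooled, confidence_S)  # (N, 3)
        fused = None
        for s, proj_s in enumerate(projected):
            term = proj_s * ws[:, s : s + 1]
            fused = term if fused is None else fused + term
        return fused, ws


def cmfs_scale(fused, confidence_S, kappa: float = 0.5):
    """Confidence-modulated feature scaling: fused * (kappa + (1-kappa) S)."""
    s_arr = np.atleast_1d(np.asarray(as_tensor(confidence_S).data, dtype=float))
    if (s_arr < 0).any() or (s_arr > 1).any():
        raise ValueError("confidence S must lie in [0, 1]")
    fused = as_tensor(fused)
    s = as_tensor(np.asarray(as_tensor(confidence_S).data).astype(fused.data.dtype))
    gain = kappa + (1.0 - kappa) * s
    if fused.ndim == 2:
        gain = gain.reshape(-1, 1)
    return fused * gain


class ClsNet(nn.Module):
    """DiagNeXt-Cls: HMRP pathways -> CAFF -> CMFS -> evidential head."""

    def __init__(self, cfg: ClsNetConfig = ClsNetConfig()):
        super().__init__()
        self.cfg = cfg
        self.pathways = nn.ModuleList([Pathway(pc) for pc in cfg.hmrp.streams])
        widths = [p.out_width for p in self.pathways]
        self.caff = CAFF(widths, cfg.fused_width, cfg.attn_hidden)
        self.head_drop = nn.Dropout(cfg.dropout)
        self.head = nn.Linear(cfg.fused_width, K_CLASSES)

    def forward_tensor(self, patches: np.ndarray, confidence_S) -> Tensor:
        """Dirichlet concentrations (N, 4) as a tracked tensor."""
        fine, medium, coarse = hmrp_streams(patches, self.cfg.hmrp)
        s_arr = np.atleast_1d(np.asarray(as_tensor(confidence_S).data)).astype(fine.dtype)
        s = as_tensor(s_arr)
        maps = []
        for stream, pathway in zip((fine, medium, coarse), self.pathways):
            _, fmap = pathway(stream)
            maps.append(fmap)
        fused, self.last_stream_weights = self.caff(maps, s)
        fused = cmfs_scale(fused, s, self.cfg.kappa)
        evidence = self.head(self.head_drop(fused)).softplus()
        return evidence + 1.0

    def forward(self, patch: np.ndarray, confidence_S: float) -> DirichletPrediction:
        alpha = self.forward_tensor(patch, confidence_S)
        if alpha.shape[0] != 1:
            raise ValueError("forward() is single-ROI; use forward_tensor for batches")
        return DirichletPrediction(alpha.data[0])

    def predict_batch(self, patches: np.ndarray, confidence_S) -> list[DirichletPrediction]:
        alpha = self.forward_tensor(patches, confidence_S)
        return [DirichletPrediction(a) for a in alpha.data]
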