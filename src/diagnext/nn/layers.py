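"""Minimal neural-network module system over the autodiff tensors."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Parameter, Tensor, as_tensor

__all__ = [
    "Module",
    "ModuleList",
    "Linear",
    "PointwiseConv3d",
    "DepthwiseConv3d",
    "Conv3d",
    "GroupNorm",
    "Dropout",
    "SE3D",
]


class Module:
    """Base class: tracks parameters/submodules in attribute order."""

    def __init__(self):
        self._training = True

    # -- discovery ------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if name.startswith("_") and name != "_modules":
                continue
            full = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(prefix=full + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for val in vars(self).values():
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield from item.modules()

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- train / eval ---------------------------------------------------
    def train(self, mode: bool = True):
        for m in self.modules():
            m._training = mode
        return self

    def eval(self):
        return self.train(False)

    @property
    def training(self) -> bool:
        return self._training

    # -- state ----------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"state dict mismatch: {sorted(missing)[:5]} ...")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=p.data.dtype).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def astype(self, dtype):
        """Cast all parameters in place (e.g. np.float32 for fast training)."""
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods):
        super().__init__()
        self.items = list(mods)

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        lim = np.sqrt(6.0 / (in_features + out_features))
        self.weight = Parameter(np.random.default_rng(0).uniform(-lim, lim, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = as_tensor(x) @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class PointwiseConv3d(Module):
    """1x1x1 cross-channel convolution."""

    def __init__(self, in_channels: int, out_channels: int, bias: bool = True):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        lim = np.sqrt(6.0 / (in_channels + out_channels))
        self.weight = Parameter(np.random.default_rng(0).uniform(-lim, lim, (out_channels, in_channels)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {x.shape[1]}")
        return F.pointwise_conv3d(x, self.weight, self.bias)


class DepthwiseConv3d(Module):
    """Per-channel 'same' spatial convolution with an odd kernel."""

    def __init__(self, channels: int, kernel_size=(7, 7, 3), bias: bool = True):
        super().__init__()
        self.channels = channels
        self.kernel_size = tuple(kernel_size)
        fan_in = int(np.prod(self.kernel_size))
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(np.random.default_rng(0).normal(0.0, std, (channels,) + self.kernel_size))
        self.bias = Parameter(np.zeros(channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        return F.depthwise_conv3d(x, self.weight, self.bias)


class Conv3d(Module):
    """Dense convolution (used for downsampling and dilated ASPP branches)."""

    def __init__(self, in_channels, out_channels, kernel_size, stride=1, dilation=1,
                 padding="same", bias: bool = True):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size if isinstance(kernel_size, tuple) else (kernel_size,) * 3
        self.stride = stride
        self.dilation = dilation
        self.padding = padding
        fan_in = in_channels * int(np.prod(self.kernel_size))
        fan_out = out_channels * int(np.prod(self.kernel_size))
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        self.weight = Parameter(
            np.random.default_rng(0).uniform(-lim, lim, (out_channels, in_channels) + self.kernel_size)
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {x.shape[1]}")
        return F.conv3d(x, self.weight, self.bias, stride=self.stride,
                        dilation=self.dilation, padding=self.padding)


class GroupNorm(Module):
    def __init__(self, channels: int, groups: int | None = None, eps: float = 1e-5):
        super().__init__()
        self.channels = channels
        self.groups = min(8, channels) if groups is None else groups
        if channels % self.groups:
            raise ValueError("channels must be divisible by groups")
        self.eps = eps
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[:2]
        sp = x.shape[2:]
        g = self.groups
        xg = x.reshape(n, g, -1)
        mu = xg.mean(axis=2, keepdims=True)
        xc = xg - mu
        var = (xc * xc).mean(axis=2, keepdims=True)
        xn = xc / (var + self.eps).sqrt()
        xn = xn.reshape((n, c) + sp)
        shape = (1, c) + (1,) * len(sp)
        return xn * self.weight.reshape(shape) + self.bias.reshape(shape)


class Dropout(Module):
    def __init__(self, p: float = 0.1):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self._rng = np.random.default_rng(0)

    def seed(self, seed: int) -> None:
        self._rng = np.random.default_rng(seed)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return as_tensor(x)
        keep = 1.0 - self.p
        mask = ((self._rng.random(x.shape) < keep) / keep).astype(x.data.dtype)
        return as_tensor(x) * Tensor(mask)


class SE3D(Module):
    """Squeeze-and-excitation channel gating for volumetric features."""

    def __init__(self, channels: int, reduction: int = 4):
        super().__init__()
        if channels < reduction:
            raise ValueError("channels must be >= reduction")
        hidden = max(1, channels // reduction)
        self.fc1 = Linear(channels, hidden)
        self.fc2 = Linear(hidden, channels)

    def gates(self, x: Tensor) -> Tensor:
        z = F.global_avg_pool(x)
        return self.fc2(self.fc1(z).relu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        s = self.gates(x)
        n, c = s.shape
        return as_tensor(x) * s.reshape(n, c, 1, 1, 1)
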