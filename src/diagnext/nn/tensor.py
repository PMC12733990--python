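"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine: every operation records its parents and a
closure that maps the output gradient to parent gradients.  ``backward``
topologically sorts the tape and accumulates gradients.  Only the
operations needed by the segmentation / classification networks and
their objectives are provided; each has an exact analytic adjoint and is
covered by finite-difference gradient checks in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy import special as sps

__all__ = ["Tensor", "Parameter", "as_tensor", "concatenate", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the adjoint of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward = backward

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS post-order
        visiting: list[tuple[Tensor, bool]] = [(self, False)]
        while visiting:
            node, processed = visiting.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            visiting.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    visiting.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if pg is None:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg
                # interior nodes that are themselves leaves of interest
            if node.requires_grad and node._parents:
                node.grad = g if node.grad is None else node.grad + g

    # -- arithmetic -----------------------------------------------------
    # python-number operands take a fast path that (a) records no gradient
    # for the constant and (b) keeps float32 data float32 (numpy treats
    # python scalars as weakly typed, while 0-d arrays would promote)

    def __add__(self, other):
        if isinstance(other, (int, float)):
            return _result(self.data + other, (self,), lambda g: ((self, g),))
        other = as_tensor(other)
        out_data = self.data + other.data

        def bw(g):
            return ((self, _unbroadcast(g, self.shape)), (other, _unbroadcast(g, other.shape)))

        return _result(out_data, (self, other), bw)

    __radd__ = __add__

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return _result(self.data - other, (self,), lambda g: ((self, g),))
        other = as_tensor(other)
        out_data = self.data - other.data

        def bw(g):
            return ((self, _unbroadcast(g, self.shape)), (other, _unbroadcast(-g, other.shape)))

        return _result(out_data, (self, other), bw)

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            return _result(other - self.data, (self,), lambda g: ((self, -g),))
        return as_tensor(other).__sub__(self)

    def __neg__(self):
        return _result(-self.data, (self,), lambda g: ((self, -g),))

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return _result(self.data * other, (self,), lambda g: ((self, g * other),))
        other = as_tensor(other)
        out_data = self.data * other.data

        def bw(g):
            return (
                (self, _unbroadcast(g * other.data, self.shape)),
                (other, _unbroadcast(g * self.data, other.shape)),
            )

        return _result(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            inv = 1.0 / other
            return _result(self.data * inv, (self,), lambda g: ((self, g * inv),))
        other = as_tensor(other)
        out_data = self.data / other.data

        def bw(g):
            return (
                (self, _unbroadcast(g / other.data, self.shape)),
                (other, _unbroadcast(-g * self.data / other.data**2, other.shape)),
            )

        return _result(out_data, (self, other), bw)

    def __rtruediv__(self, other):
        if isinstance(other, (int, float)):
            out_data = other / self.data

            def bw(g):
                return ((self, -g * out_data / self.data),)

            return _result(out_data, (self,), bw)
        return as_tensor(other).__truediv__(self)

    def __pow__(self, p: float):
        out_data = self.data**p

        def bw(g):
            return ((self, g * p * self.data ** (p - 1)),)

        return _result(out_data, (self,), bw)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def bw(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return ((self, _unbroadcast(ga, self.shape)), (other, _unbroadcast(gb, other.shape)))

        return _result(out_data, (self, other), bw)

    # -- elementwise nonlinearities ------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return _result(out_data, (self,), lambda g: ((self, g * out_data),))

    def log(self):
        return _result(np.log(self.data), (self,), lambda g: ((self, g / self.data),))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return _result(out_data, (self,), lambda g: ((self, g * 0.5 / out_data),))

    def sigmoid(self):
        out_data = sps.expit(self.data)
        return _result(out_data, (self,), lambda g: ((self, g * out_data * (1.0 - out_data)),))

    def tanh(self):
        out_data = np.tanh(self.data)
        return _result(out_data, (self,), lambda g: ((self, g * (1.0 - out_data**2)),))

    def relu(self):
        out_data = np.maximum(self.data, 0.0)
        return _result(out_data, (self,), lambda g: ((self, g * (self.data > 0)),))

    def gelu(self):
        # exact (erf) form; python-float constants keep float32 inputs float32
        x = self.data
        cdf = 0.5 * (1.0 + sps.erf(x * float(1.0 / np.sqrt(2.0))))
        out_data = x * cdf

        def bw(g):
            pdf = np.exp(-0.5 * x**2) * float(1.0 / np.sqrt(2.0 * np.pi))
            return ((self, g * (cdf + x * pdf)),)

        return _result(out_data, (self,), bw)

    def silu(self):
        s = sps.expit(self.data)
        out_data = self.data * s

        def bw(g):
            return ((self, g * (s + self.data * s * (1.0 - s))),)

        return _result(out_data, (self,), bw)

    def softplus(self):
        out_data = np.logaddexp(0.0, self.data)
        return _result(out_data, (self,), lambda g: ((self, g * sps.expit(self.data)),))

    def clip(self, lo: float | None, hi: float | None):
        """Clamp values; gradient flows only through the unclipped region."""
        out_data = np.clip(self.data, lo, hi)
        mask = np.ones_like(self.data)
        if lo is not None:
            mask = mask * (self.data >= lo)
        if hi is not None:
            mask = mask * (self.data <= hi)
        return _result(out_data, (self,), lambda g: ((self, g * mask),))

    def digamma(self):
        out_data = sps.digamma(self.data)
        return _result(out_data, (self,), lambda g: ((self, g * sps.polygamma(1, self.data)),))

    def gammaln(self):
        out_data = sps.gammaln(self.data)
        return _result(out_data, (self,), lambda g: ((self, g * sps.digamma(self.data)),))

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is None:
                return ((self, np.broadcast_to(g, self.shape).copy()),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                for a in sorted(a % self.ndim for a in ax):
                    g = np.expand_dims(g, a)
            return ((self, np.broadcast_to(g, self.shape).copy()),)

        return _result(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) / n

    def max_detached(self, axis=None, keepdims=False) -> np.ndarray:
        """Max of the underlying values, not tracked by the tape."""
        return self.data.max(axis=axis, keepdims=keepdims)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            return ((self, out_data * (g - dot)),)

        return _result(out_data, (self,), bw)

    def log_softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out_data = z - lse
        sm = np.exp(out_data)

        def bw(g):
            return ((self, g - sm * g.sum(axis=axis, keepdims=True)),)

        return _result(out_data, (self,), bw)

    # -- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        orig = self.shape
        return _result(out_data, (self,), lambda g: ((self, g.reshape(orig)),))

    def transpose(self, axes):
        out_data = self.data.transpose(axes)
        inv = np.argsort(axes)
        return _result(out_data, (self,), lambda g: ((self, g.transpose(inv)),))

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return ((self, full),)

        return _result(out_data, (self,), bw)

    def pad(self, pad_width):
        out_data = np.pad(self.data, pad_width)
        sl = tuple(slice(lo, lo + s) for (lo, _), s in zip(pad_width, self.shape))
        return _result(out_data, (self,), lambda g: ((self, g[sl]),))


def _result(data, parents, backward) -> Tensor:
    track = any(isinstance(p, Tensor) and (p.requires_grad or p._parents or p._backward) for p in parents)
    if track:
        return Tensor(data, parents=parents, backward=backward)
    return Tensor(data)


class Parameter(Tensor):
    """A leaf tensor that optimizers update."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        parts = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, parts))

    return _result(out_data, tuple(tensors), bw)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def bw(g):
        parts = np.split(g, len(tensors), axis=axis)
        return tuple((t, np.squeeze(p, axis=axis)) for t, p in zip(tensors, parts))

    return _result(out_data, tuple(tensors), bw)
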