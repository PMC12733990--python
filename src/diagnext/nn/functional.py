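"""Differentiable 3D convolution and resampling primitives.

Layout convention everywhere: ``(N, C, D, H, W)`` where ``D, H`` are the
in-plane axes and ``W`` is the through-plane axis (matching the package's
(in-plane, in-plane, through-plane) volume convention).

Two convolution paths are provided:

* ``conv3d`` — generic dense convolution (any stride/dilation) computed by
  the shift-and-matmul decomposition: one pointwise contraction per kernel
  offset.  Exact, memory-light, used for 1x1x1 / strided / dilated convs
  and as the reference implementation in tests.
* ``depthwise_conv3d`` — per-channel 'same' correlation computed with FFTs
  batched over (N, C).  This is the hot path for the large 7x7x3 / 5x5x3
  depthwise kernels; tests pin it against the shift-based reference.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import fft as sfft

from .tensor import Tensor, _result, as_tensor

__all__ = [
    "conv3d",
    "depthwise_conv3d",
    "pointwise_conv3d",
    "linear_resize3d",
    "global_avg_pool",
]


def _triple(v):
    if isinstance(v, (tuple, list)):
        return tuple(int(x) for x in v)
    return (int(v),) * 3


# ----------------------------------------------------------------------
# generic shift-based convolution
# ----------------------------------------------------------------------

def conv3d(x, w, b=None, stride=1, dilation=1, padding="same"):
    """Cross-correlation of ``x (N,Cin,D,H,W)`` with ``w (Cout,Cin,kd,kh,kw)``.

    ``padding='same'`` (stride 1 only) preserves spatial shape; an explicit
    triple pads both sides.  Output spatial size per axis is
    ``(in + 2p - dil*(k-1) - 1)//stride + 1``.
    """
    x = as_tensor(x)
    w = as_tensor(w)
    stride = _triple(stride)
    dilation = _triple(dilation)
    kd, kh, kw = w.shape[2:]
    if padding == "same":
        if stride != (1, 1, 1):
            raise ValueError("'same' padding requires stride 1")
        pads = tuple(d * (k - 1) // 2 for d, k in zip(dilation, (kd, kh, kw)))
    else:
        pads = _triple(padding)
    for ax, (dim, d, k) in enumerate(zip(x.shape[2:], dilation, (kd, kh, kw))):
        if dim + 2 * pads[ax] < d * (k - 1) + 1:
            raise ValueError(
                f"spatial axis {ax} (size {dim}) smaller than dilated kernel span {d * (k - 1) + 1}"
            )
    xd = x.data
    n, cin = xd.shape[:2]
    cout = w.shape[0]
    pad_width = ((0, 0), (0, 0)) + tuple((p, p) for p in pads)
    xp = np.pad(xd, pad_width)
    out_sp = tuple(
        (xd.shape[2 + i] + 2 * pads[i] - dilation[i] * ((kd, kh, kw)[i] - 1) - 1) // stride[i] + 1
        for i in range(3)
    )
    wd = w.data
    out = np.zeros((n, cout) + out_sp, dtype=np.result_type(xd, wd))
    for i in range(kd):
        for j in range(kh):
            for k in range(kw):
                sl = tuple(
                    slice(off * dil, off * dil + st * (sz - 1) + 1, st)
                    for off, dil, st, sz in zip((i, j, k), dilation, stride, out_sp)
                )
                patch = xp[(slice(None), slice(None)) + sl]
                out += np.einsum("ncdhw,oc->nodhw", patch, wd[:, :, i, j, k], optimize=True)
    if b is not None:
        b = as_tensor(b)
        out = out + b.data.reshape(1, cout, 1, 1, 1)

    def bw(g):
        gw = np.zeros_like(wd)
        gxp = np.zeros_like(xp)
        for i in range(kd):
            for j in range(kh):
                for k in range(kw):
                    sl = tuple(
                        slice(off * dil, off * dil + st * (sz - 1) + 1, st)
                        for off, dil, st, sz in zip((i, j, k), dilation, stride, out_sp)
                    )
                    idx = (slice(None), slice(None)) + sl
                    patch = xp[idx]
                    gw[:, :, i, j, k] = np.einsum("nodhw,ncdhw->oc", g, patch, optimize=True)
                    gxp[idx] += np.einsum("nodhw,oc->ncdhw", g, wd[:, :, i, j, k], optimize=True)
        crop = (slice(None), slice(None)) + tuple(
            slice(p, p + s) for p, s in zip(pads, xd.shape[2:])
        )
        grads = [(x, gxp[crop]), (w, gw)]
        if b is not None:
            grads.append((b, g.sum(axis=(0, 2, 3, 4))))
        return tuple(grads)

    parents = (x, w) if b is None else (x, w, b)
    return _result(out, parents, bw)


def pointwise_conv3d(x, w, b=None):
    """1x1x1 convolution: pure channel mixing. ``w`` has shape (Cout, Cin)."""
    x = as_tensor(x)
    w = as_tensor(w)
    out = np.einsum("ncdhw,oc->nodhw", x.data, w.data, optimize=True)
    if b is not None:
        b = as_tensor(b)
        out = out + b.data.reshape(1, -1, 1, 1, 1)

    def bw(g):
        gx = np.einsum("nodhw,oc->ncdhw", g, w.data, optimize=True)
        gw = np.einsum("nodhw,ncdhw->oc", g, x.data, optimize=True)
        grads = [(x, gx), (w, gw)]
        if b is not None:
            grads.append((b, g.sum(axis=(0, 2, 3, 4))))
        return tuple(grads)

    parents = (x, w) if b is None else (x, w, b)
    return _result(out, parents, bw)


# ----------------------------------------------------------------------
# FFT depthwise convolution ('same', stride 1)
# ----------------------------------------------------------------------

def depthwise_conv3d(x, w, b=None):
    """Per-channel 'same' correlation. ``w`` has shape (C, kd, kh, kw).

    Computed with circular FFTs of size >= spatial + kernel - 1, which
    makes every circular product below exactly linear:

    * forward         y  = IFFT(X . conj(W))  sliced at [0, s)
    * input gradient  gx = IFFT(G . W)        sliced at [pad, pad + s)
    * kernel gradient gw = IFFT(X . conj(G))  sliced at [0, k), summed over N

    where X transforms the input padded low by ``pad`` and G / W transform
    the output gradient / kernel embedded at the origin.  X and W are
    cached from the forward pass and reused by the backward closure.
    """
    x = as_tensor(x)
    w = as_tensor(w)
    ksp = w.shape[1:]
    sp = x.shape[2:]
    pads = tuple((k - 1) // 2 for k in ksp)
    axes = (-3, -2, -1)
    fshape = tuple(sfft.next_fast_len(s + k - 1) for s, k in zip(sp, ksp))
    xd, wd = x.data, w.data
    pad_width = ((0, 0), (0, 0)) + tuple((p, 0) for p in pads)
    X = sfft.rfftn(np.pad(xd, pad_width), s=fshape, axes=axes)
    W = sfft.rfftn(wd, s=fshape, axes=axes)
    lead = (slice(None), slice(None))
    out = sfft.irfftn(X * W.conj()[None], s=fshape, axes=axes)[lead + tuple(slice(0, s) for s in sp)]
    out = np.ascontiguousarray(out)
    if b is not None:
        b = as_tensor(b)
        out = out + b.data.reshape(1, -1, 1, 1, 1)

    def bw(g):
        G = sfft.rfftn(g, s=fshape, axes=axes)
        gx = sfft.irfftn(G * W[None], s=fshape, axes=axes)[
            lead + tuple(slice(p, p + s) for p, s in zip(pads, sp))
        ]
        gw = sfft.irfftn(X * G.conj(), s=fshape, axes=axes)[
            lead + tuple(slice(0, k) for k in ksp)
        ].sum(axis=0)
        grads = [(x, np.ascontiguousarray(gx)), (w, gw)]
        if b is not None:
            grads.append((b, g.sum(axis=(0, 2, 3, 4))))
        return tuple(grads)

    parents = (x, w) if b is None else (x, w, b)
    return _result(out, parents, bw)


# ----------------------------------------------------------------------
# trilinear resize
# ----------------------------------------------------------------------

@lru_cache(maxsize=None)
def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense 1D linear interpolation matrix (n_out x n_in), half-pixel centers."""
    M = np.zeros((n_out, n_in))
    if n_in == 1:
        M[:, 0] = 1.0
        return M
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0.0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    t = src - lo
    M[np.arange(n_out), lo] += 1.0 - t
    M[np.arange(n_out), hi] += t
    return M


def _apply_axis(arr: np.ndarray, M: np.ndarray, axis: int) -> np.ndarray:
    M = M.astype(arr.dtype, copy=False)
    return np.moveaxis(np.tensordot(M, np.moveaxis(arr, axis, 0), axes=(1, 0)), 0, axis)


def linear_resize3d(x, out_shape):
    """Trilinear resize of the spatial axes of (N, C, D, H, W)."""
    x = as_tensor(x)
    out_shape = tuple(int(s) for s in out_shape)
    mats = [_interp_matrix(x.shape[2 + i], out_shape[i]) for i in range(3)]
    out = x.data
    for i, M in enumerate(mats):
        out = _apply_axis(out, M, 2 + i)

    def bw(g):
        gx = g
        for i, M in enumerate(mats):
            gx = _apply_axis(gx, M.T, 2 + i)
        return ((x, gx),)

    return _result(out, (x,), bw)


def global_avg_pool(x) -> Tensor:
    """(N, C, D, H, W) -> (N, C) spatial mean."""
    return as_tensor(x).mean(axis=(2, 3, 4))
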