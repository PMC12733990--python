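"""Independent brute-force oracles shared across test modules.

Everything here is deliberately naive (explicit loops, all-pairs scans)
and never calls into the package's own implementations.
"""

import numpy as np


def direct_conv3d(x, w, stride=1, dilation=1, pads=(0, 0, 0)):
    """Dense correlation by explicit loops over every output voxel."""
    n, cin, D, H, W = x.shape
    cout, _, kd, kh, kw = w.shape
    s = (stride,) * 3 if np.isscalar(stride) else tuple(stride)
    d = (dilation,) * 3 if np.isscalar(dilation) else tuple(dilation)
    xp = np.pad(x, ((0, 0), (0, 0)) + tuple((p, p) for p in pads))
    out_sp = tuple(
        (x.shape[2 + i] + 2 * pads[i] - d[i] * ((kd, kh, kw)[i] - 1) - 1) // s[i] + 1
        for i in range(3)
    )
    out = np.zeros((n, cout) + out_sp)
    for b in range(n):
        for o in range(cout):
            for zi in range(out_sp[0]):
                for yi in range(out_sp[1]):
                    for xi in range(out_sp[2]):
                        acc = 0.0
                        for c in range(cin):
                            for i in range(kd):
                                for j in range(kh):
                                    for k in range(kw):
                                        acc += (
                                            w[o, c, i, j, k]
                                            * xp[b, c, zi * s[0] + i * d[0],
                                                 yi * s[1] + j * d[1], xi * s[2] + k * d[2]]
                                        )
                        out[b, o, zi, yi, xi] = acc
    return out


def brute_signed_distance(mask):
    """All-pairs signed Euclidean distance (voxel units).

    Outside voxels: +min distance to any inside voxel; inside voxels:
    -min distance to any outside voxel.  Requires a non-degenerate mask.
    """
    m = np.asarray(mask).astype(bool)
    coords = np.argwhere(np.ones_like(m))
    inside = np.argwhere(m)
    outside = np.argwhere(~m)
    out = np.zeros(m.shape, dtype=float)
    for c in coords:
        if m[tuple(c)]:
            d = np.sqrt(((outside - c) ** 2).sum(axis=1)).min()
            out[tuple(c)] = -d
        else:
            d = np.sqrt(((inside - c) ** 2).sum(axis=1)).min()
            out[tuple(c)] = d
    return out


def flood_fill_components(mask, min_size=0):
    """26-connectivity components by explicit flood fill.

    Returns a list of frozensets of voxel index triples, ordered by
    (size descending, lexicographic minimum voxel).
    """
    m = np.asarray(mask).astype(bool)
    seen = np.zeros_like(m)
    comps = []
    offsets = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    for start in np.argwhere(m & ~seen):
        start = tuple(start)
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            v = stack.pop()
            comp.append(v)
            for off in offsets:
                nb = tuple(v[i] + off[i] for i in range(3))
                if all(0 <= nb[i] < m.shape[i] for i in range(3)) and m[nb] and not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        if len(comp) >= min_size:
            comps.append(frozenset(comp))
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def surface_voxels(mask):
    """Voxels of the region with at least one 6-neighbour outside."""
    m = np.asarray(mask).astype(bool)
    out = []
    for v in np.argwhere(m):
        v = tuple(v)
        boundary = False
        for ax in range(3):
            for d in (-1, 1):
                nb = list(v)
                nb[ax] += d
                nb = tuple(nb)
                if not (0 <= nb[ax] < m.shape[ax]) or not m[nb]:
                    boundary = True
        if boundary:
            out.append(v)
    return np.array(out)


def brute_hd95(a, b, spacing=(1.0, 1.0, 1.0)):
    """95th percentile of pooled symmetric surface distances (mm)."""
    sa = surface_voxels(a) * np.asarray(spacing)
    sb = surface_voxels(b) * np.asarray(spacing)
    if len(sa) == 0 and len(sb) == 0:
        return 0.0
    d_ab = [np.sqrt(((sb - p) ** 2).sum(axis=1)).min() for p in sa]
    d_ba = [np.sqrt(((sa - p) ** 2).sum(axis=1)).min() for p in sb]
    return float(np.percentile(np.array(d_ab + d_ba), 95))


def dice_counting(a, b):
    """Dice from explicit voxel-set counts."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * (a & b).sum() / denom
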