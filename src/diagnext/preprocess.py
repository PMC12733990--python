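"""Volume preprocessing applied before segmentation.

The protocol: kidney window (width 400 / level 40 HU) rescaled to [0, 1],
resampling to 1.0 x 1.0 x 2.5 mm voxels, three-stage intensity
normalization (global z-score, organ z-score within the kidney mask,
local patch standardization), padding to multiples of 16 and, for very
shallow stacks, cubic B-spline slice interpolation up to a minimum depth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import interpolate, ndimage

from .exceptions import MetadataError, SizingError
from .phantom import LabeledVolume

__all__ = [
    "PreprocessConfig",
    "hu_window",
    "resample",
    "normalize_three_stage",
    "pad_to_multiple",
    "unpad",
    "interpolate_slices",
    "bias_field_correction",
    "preprocess_volume",
]


@dataclass(frozen=True)
class PreprocessConfig:
    window_width_hu: float = 400.0
    window_level_hu: float = 40.0
    target_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 2.5)
    pad_multiple: int = 16
    min_depth_slices: int = 8
    patch_size: int = 16  # stage-3 local standardization window
    bias_correction: bool = False  # hook; no-op (phantoms carry no bias field)

    def __post_init__(self):
        if self.window_width_hu <= 0:
            raise ValueError("window width must be positive")
        if any(s <= 0 for s in self.target_spacing_mm):
            raise MetadataError("target spacing must be strictly positive")
        if self.pad_multiple < 1:
            raise ValueError("pad_multiple must be >= 1")


def hu_window(image: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Clip to [level - width/2, level + width/2] and rescale to [0, 1]."""
    lo = cfg.window_level_hu - cfg.window_width_hu / 2.0
    hi = cfg.window_level_hu + cfg.window_width_hu / 2.0
    return (np.clip(image, lo, hi) - lo) / (hi - lo)


def _resize(arr: np.ndarray, out_shape, order: int) -> np.ndarray:
    """Resize with half-pixel-centre sampling (trilinear or nearest)."""
    out_shape = tuple(int(s) for s in out_shape)
    if out_shape == arr.shape:
        return arr.astype(np.float64) if order > 0 else arr.copy()
    coords = np.meshgrid(
        *[(np.arange(o) + 0.5) * n / o - 0.5 for o, n in zip(out_shape, arr.shape)],
        indexing="ij",
    )
    return ndimage.map_coordinates(arr.astype(np.float64), np.stack(coords), order=order, mode="nearest")


def resample(v: LabeledVolume, cfg: PreprocessConfig = PreprocessConfig()) -> LabeledVolume:
    """Resample image (trilinear) and mask (nearest) to the target spacing."""
    if any(s <= 0 for s in v.spacing_mm):
        raise MetadataError("input spacing must be strictly positive")
    target = cfg.target_spacing_mm
    out_shape = tuple(
        int(round(n * s / t)) for n, s, t in zip(v.image.shape, v.spacing_mm, target)
    )
    img = _resize(v.image, out_shape, order=1)
    msk = _resize(v.mask, out_shape, order=0)
    return LabeledVolume(img.astype(np.float32), msk.astype(np.uint8), target,
                         v.patient_id, list(v.lesions), v.interpolated)


def _zscore(arr: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    sd = arr.std()
    if sd < eps:
        return np.zeros_like(arr)
    return (arr - arr.mean()) / sd


def normalize_three_stage(image: np.ndarray, kidney_mask: np.ndarray | None = None,
                          patch_size: int = 16, eps: float = 1e-6) -> np.ndarray:
    """Global z-score, organ-specific recentering, local patch standardization.

    Stage 3 standardizes overlapping cubic patches (stride = half side,
    truncated at volume edges) and mean-blends the overlaps.
    """
    out = _zscore(image.astype(np.float64), eps)
    if kidney_mask is not None and kidney_mask.astype(bool).any():
        sel = kidney_mask.astype(bool)
        mu, sd = out[sel].mean(), out[sel].std()
        out = (out - mu) / (sd if sd > eps else 1.0)
    # stage 3: sliding-patch standardization with mean blending
    acc = np.zeros_like(out)
    cnt = np.zeros_like(out)
    starts = []
    for dim in out.shape:
        side = min(patch_size, dim)
        stride = max(1, side // 2)
        ax = list(range(0, dim - side + 1, stride))
        if ax[-1] != dim - side:
            ax.append(dim - side)
        starts.append([(a, side) for a in ax])
    for a0, s0 in starts[0]:
        for a1, s1 in starts[1]:
            for a2, s2 in starts[2]:
                sl = (slice(a0, a0 + s0), slice(a1, a1 + s1), slice(a2, a2 + s2))
                patch = out[sl]
                sd = patch.std()
                z = (patch - patch.mean()) / sd if sd > eps else np.zeros_like(patch)
                acc[sl] += z
                cnt[sl] += 1.0
    return acc / cnt


def pad_to_multiple(arr: np.ndarray, multiple: int = 16):
    """Symmetric zero-pad each axis to the next multiple (extra voxel high side).

    Returns ``(padded, record)`` where ``record`` inverts the padding exactly.
    """
    pad = []
    for dim in arr.shape:
        target = int(np.ceil(dim / multiple)) * multiple
        extra = target - dim
        pad.append((extra // 2, extra - extra // 2))
    return np.pad(arr, pad), tuple(pad)


def unpad(arr: np.ndarray, record) -> np.ndarray:
    sl = tuple(slice(lo, arr.shape[i] - hi) for i, (lo, hi) in enumerate(record))
    return arr[sl]


def interpolate_slices(v: LabeledVolume, min_depth: int = 8) -> LabeledVolume:
    """Bring shallow stacks up to ``min_depth`` through-plane slices.

    The image is interpolated with a cubic B-spline along the through-plane
    axis (endpoint-preserving sample positions, exact for linear profiles);
    the mask uses nearest neighbour.  Deeper stacks pass through unchanged.
    """
    depth = v.image.shape[2]
    if depth < 2:
        raise SizingError("need at least 2 slices to interpolate")
    if depth >= min_depth:
        return replace(v, interpolated=False)
    z_old = np.arange(depth, dtype=float)
    z_new = np.linspace(0.0, depth - 1.0, min_depth)
    k = min(3, depth - 1)  # cubic where the stack allows, lower order below 4 slices
    spline = interpolate.make_interp_spline(z_old, v.image.astype(np.float64), k=k, axis=2)
    img = spline(z_new)
    nearest = np.clip(np.round(z_new).astype(int), 0, depth - 1)
    msk = v.mask[:, :, nearest]
    new_spacing = (v.spacing_mm[0], v.spacing_mm[1], v.spacing_mm[2] * (depth - 1) / (min_depth - 1))
    return LabeledVolume(img.astype(np.float32), msk.astype(np.uint8), new_spacing,
                         v.patient_id, list(v.lesions), interpolated=True)


def bias_field_correction(image: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Configurable hook for scanner bias-field correction; identity here."""
    return image


def preprocess_volume(v: LabeledVolume, cfg: PreprocessConfig = PreprocessConfig()):
    """Full protocol; returns (normalized image, mask, pad record, volume)."""
    if v.image.shape[2] < cfg.min_depth_slices:
        v = interpolate_slices(v, cfg.min_depth_slices)
    v = resample(v, cfg)
    img = bias_field_correction(v.image, cfg)
    img = hu_window(img, cfg)
    img = normalize_three_stage(img, v.mask == 1, patch_size=cfg.patch_size)
    img, rec = pad_to_multiple(img, cfg.pad_multiple)
    msk, _ = pad_to_multiple(v.mask, cfg.pad_multiple)
    return img.astype(np.float32), msk.astype(np.uint8), rec, v
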