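"""Synthetic contrast-CT kidney phantoms with voxel-accurate ground truth.

Each phantom patient is a single axis-aligned smooth ellipsoidal kidney
(label 1) embedded in soft-tissue background, optionally carrying one or
more lesions of a single pathology class:

* cysts    — hypodense, well-circumscribed spheres with smooth borders;
* tumors   — heterogeneous perturbed ellipsoids with irregular margins
             (low-order spherical-harmonic radius perturbation) whose
             interior mixes two enhancement levels in smooth patches;
* stones   — small hyperdense spherical calcifications.

Intensities are Hounsfield-like.  Voxel (i, j, k) is located at
``(i, j, k) * spacing_mm`` (axis order: in-plane, in-plane, through-plane).
Every output is a pure function of ``(spec, seed, patient_id)``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage, special

from .exceptions import SizingError

__all__ = [
    "CLASS_NAMES",
    "CLASS_LABELS",
    "PhantomSpec",
    "LesionInfo",
    "LabeledVolume",
    "DatasetSplit",
    "AugmentParams",
    "generate_phantom",
    "generate_cohort",
    "split_patients",
    "augment",
    "apply_augmentation",
    "write_dataset",
    "read_dataset",
]

# patient-level pathology classes and their mask labels
CLASS_NAMES = ("normal", "cyst", "tumor", "stone")
CLASS_LABELS = {"cyst": 2, "tumor": 3, "stone": 4}
LABEL_NAMES = {0: "background", 1: "kidney", 2: "cyst", 3: "tumor", 4: "stone"}

# cohort class proportions from the study population composition tables
from .study_tables import cohort_class_proportions as _cohort_props

_DEFAULT_MIX = tuple(_cohort_props()[c] for c in ("normal", "cyst", "tumor", "stone"))


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for a phantom cohort."""

    volume_shape: tuple[int, int, int] = (64, 64, 16)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 2.5)
    class_mix: tuple[float, float, float, float] = _DEFAULT_MIX
    lesion_radius_range_mm: dict = field(
        default_factory=lambda: {"cyst": (5.0, 10.0), "tumor": (6.0, 12.0), "stone": (3.0, 5.0)}
    )
    hu_params: dict = field(
        default_factory=lambda: {
            "background": (-80.0, 20.0),
            "kidney": (110.0, 15.0),
            "cyst": (10.0, 8.0),
            "tumor": ((60.0, 140.0), 20.0),
            "stone": (700.0, 150.0),
        }
    )
    noise_std: float = 5.0
    n_lesions: int = 1
    seed: int = 0

    def __post_init__(self):
        if len(self.volume_shape) != 3 or any(s < 8 for s in self.volume_shape):
            raise SizingError("volume_shape must be three axes, each >= 8 voxels")
        if any(s <= 0 for s in self.spacing_mm):
            raise SizingError("spacing must be strictly positive")
        if abs(sum(self.class_mix) - 1.0) > 1e-9 or any(p < 0 for p in self.class_mix):
            raise ValueError("class_mix must be nonnegative and sum to 1 within 1e-9")
        for cls, (lo, hi) in self.lesion_radius_range_mm.items():
            if lo <= 0 or hi < lo:
                raise SizingError(f"invalid radius interval for {cls}: ({lo}, {hi})")
        if not 1 <= self.n_lesions <= 3:
            raise SizingError("n_lesions must be in 1..3")


@dataclass(frozen=True)
class LesionInfo:
    class_name: str
    center_mm: tuple[float, float, float]
    radius_mm: float
    voxel_count: int


@dataclass
class LabeledVolume:
    """A 3D HU-like image with an aligned 5-class mask."""

    image: np.ndarray  # float32, (D, H, W)
    mask: np.ndarray  # uint8, labels {0..4}
    spacing_mm: tuple[float, float, float]
    patient_id: str
    lesions: list[LesionInfo] = field(default_factory=list)
    interpolated: bool = False

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes must match")
        if not np.isin(np.unique(self.mask), range(5)).all():
            raise ValueError("mask labels must be in {0..4}")
        if any(s <= 0 for s in self.spacing_mm):
            raise SizingError("spacing must be strictly positive")

    @property
    def patient_class(self) -> str:
        labels = set(np.unique(self.mask)) - {0, 1}
        if not labels:
            return "normal"
        return LABEL_NAMES[max(labels)]


@dataclass(frozen=True)
class DatasetSplit:
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def __post_init__(self):
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("split sets must be pairwise disjoint and duplicate-free")

    def split_of(self, pid: str) -> str:
        for name in ("train", "val", "test"):
            if pid in getattr(self, f"{name}_ids"):
                return name
        raise KeyError(pid)


# ----------------------------------------------------------------------
# generation
# ----------------------------------------------------------------------

def _patient_rng(seed: int, patient_id: str) -> np.random.Generator:
    digest = hashlib.sha256(patient_id.encode()).digest()
    return np.random.default_rng(np.random.SeedSequence([seed, int.from_bytes(digest[:8], "little")]))


def _voxel_grids(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _sph_harm_real(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Real spherical harmonic; theta polar in [0, pi], phi azimuthal."""
    y = special.sph_harm_y(l, abs(m), theta, phi)
    if m > 0:
        return np.sqrt(2.0) * y.real
    if m < 0:
        return np.sqrt(2.0) * y.imag
    return y.real


def _tumor_radius_field(rng, r0, dx, dy, dz, max_order=3, max_amp=0.3):
    """Direction-dependent radius r(theta, phi) for an irregular tumor."""
    r = np.sqrt(dx**2 + dy**2 + dz**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(np.where(r > 0, dz / np.maximum(r, 1e-9), 1.0), -1, 1))
    phi = np.arctan2(dy, dx)
    pert = np.zeros_like(r)
    for l in range(1, max_order + 1):
        for m in range(-l, l + 1):
            pert += rng.normal() * _sph_harm_real(l, m, theta, phi)
    peak = np.abs(pert).max()
    if peak > 0:
        amp = rng.uniform(0.15, max_amp)
        pert = pert / peak * amp
    return r0 * (1.0 + pert)


def generate_phantom(spec: PhantomSpec, patient_id: str, lesion_class: str | None = None) -> LabeledVolume:
    """Generate one phantom patient; deterministic in (spec, patient_id)."""
    rng = _patient_rng(spec.seed, patient_id)
    shape = tuple(spec.volume_shape)
    spacing = tuple(float(s) for s in spec.spacing_mm)
    fov = np.array([n * s for n, s in zip(shape, spacing)])
    X, Y, Z = _voxel_grids(shape, spacing)

    if lesion_class is None:
        lesion_class = rng.choice(CLASS_NAMES, p=np.asarray(spec.class_mix))
    elif lesion_class not in CLASS_NAMES:
        raise ValueError(f"unknown class {lesion_class!r}")
    else:
        rng.choice(CLASS_NAMES, p=np.asarray(spec.class_mix))  # keep stream aligned

    # kidney ellipsoid
    semi = fov * np.array([0.34, 0.30, 0.40]) * rng.uniform(0.92, 1.08, 3)
    center = fov / 2.0 + rng.uniform(-0.04, 0.04, 3) * fov
    kidney = ((X - center[0]) / semi[0]) ** 2 + ((Y - center[1]) / semi[1]) ** 2 + (
        (Z - center[2]) / semi[2]
    ) ** 2 <= 1.0
    mask = np.where(kidney, 1, 0).astype(np.uint8)

    lesions: list[LesionInfo] = []
    if lesion_class != "normal":
        lo, hi = spec.lesion_radius_range_mm[lesion_class]
        margin = max(spacing)  # one-voxel safety margin
        if hi + margin >= semi.min():
            raise SizingError(
                f"{lesion_class} radius up to {hi} mm cannot fit inside a kidney with "
                f"minimal semi-axis {semi.min():.1f} mm"
            )
        n_lesions = int(rng.integers(1, spec.n_lesions + 1))
        for _ in range(n_lesions):
            radius = float(rng.uniform(lo, hi))
            # irregular tumors may extend up to 30% past the nominal radius
            reach = radius * (1.3 if lesion_class == "tumor" else 1.0) + margin
            if reach >= semi.min():
                # clamp the radius so the full (possibly perturbed) reach fits
                factor = 1.3 if lesion_class == "tumor" else 1.0
                radius = max(float(lo), (semi.min() - margin) / factor * 0.95)
                reach = radius * factor + margin
            # rejection-sample a center whose full reach stays inside the kidney
            shrink = 1.0 - reach / semi.min()
            for _ in range(100):
                u = rng.uniform(-1, 1, 3)
                if (u**2).sum() <= 1.0:
                    break
            lcenter = center + u * semi * shrink
            dx, dy, dz = X - lcenter[0], Y - lcenter[1], Z - lcenter[2]
            if lesion_class == "tumor":
                rfield = _tumor_radius_field(rng, radius, dx, dy, dz)
                inside = np.sqrt(dx**2 + dy**2 + dz**2) <= rfield
                inside &= kidney
            else:
                inside = dx**2 + dy**2 + dz**2 <= radius**2
            label = CLASS_LABELS[lesion_class]
            mask[inside] = label
            lesions.append(
                LesionInfo(lesion_class, tuple(float(c) for c in lcenter), radius, int(inside.sum()))
            )

    # intensity model: smoothed tissue means + per-tissue noise + global noise
    hu = spec.hu_params
    mean_map = np.full(shape, hu["background"][0])
    std_map = np.full(shape, hu["background"][1])
    mean_map[mask == 1] = hu["kidney"][0]
    std_map[mask == 1] = hu["kidney"][1]
    for cls, label in CLASS_LABELS.items():
        sel = mask == label
        if not sel.any():
            continue
        if cls == "tumor":
            (m_lo, m_hi), sd = hu["tumor"]
            patches = ndimage.gaussian_filter(rng.normal(size=shape), sigma=(2.0, 2.0, 1.0))
            mean_map[sel] = np.where(patches[sel] > 0, m_hi, m_lo)
            std_map[sel] = sd
        else:
            m, sd = hu[cls]
            mean_map[sel] = m
            std_map[sel] = sd
    smooth = ndimage.gaussian_filter(mean_map, sigma=(0.7, 0.7, 0.35))
    image = smooth + std_map * rng.normal(size=shape) + spec.noise_std * rng.normal(size=shape)
    return LabeledVolume(image.astype(np.float32), mask, spacing, patient_id, lesions)


def generate_cohort(spec: PhantomSpec, n_patients: int) -> list[LabeledVolume]:
    """Generate ``n_patients`` phantoms; class per patient drawn from ``class_mix``."""
    if n_patients < 1:
        raise SizingError("n_patients must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC0407]))
    classes = rng.choice(len(CLASS_NAMES), size=n_patients, p=np.asarray(spec.class_mix))
    width = max(4, len(str(n_patients)))
    return [
        generate_phantom(spec, f"P{idx:0{width}d}", CLASS_NAMES[c])
        for idx, c in enumerate(classes)
    ]


def split_patients(ids, fractions=(0.70, 0.15, 0.15), seed: int = 42) -> DatasetSplit:
    """Patient-level split: val/test sizes are ``round(f * n)``, train the rest."""
    ids = list(ids)
    n = len(ids)
    if n < 3:
        raise SizingError("need at least 3 patients to split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_val = round(fractions[1] * n)
    n_test = round(fractions[2] * n)
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [ids[i] for i in order]
    val = tuple(shuffled[:n_val])
    test = tuple(shuffled[n_val : n_val + n_test])
    train = tuple(shuffled[n_val + n_test :])
    return DatasetSplit(train_ids=train, val_ids=val, test_ids=test)


# ----------------------------------------------------------------------
# augmentation
# ----------------------------------------------------------------------

@dataclass
class AugmentParams:
    angle_deg: float = 0.0
    elastic_field: np.ndarray | None = None  # (3, D, H, W) voxel displacements
    intensity_scale: float = 1.0
    gamma: float = 1.0


def _sample_params(shape, rng, elastic_amp_vox=1.5, elastic_sigma_vox=6.0) -> AugmentParams:
    field_ = np.stack(
        [
            ndimage.gaussian_filter(rng.normal(size=shape), sigma=elastic_sigma_vox)
            for _ in range(3)
        ]
    )
    peak = np.abs(field_).max()
    if peak > 0:
        field_ *= elastic_amp_vox / peak
    return AugmentParams(
        angle_deg=float(rng.uniform(-15.0, 15.0)),
        elastic_field=field_,
        intensity_scale=float(rng.uniform(0.9, 1.1)),
        gamma=float(rng.uniform(0.8, 1.2)),
    )


def apply_augmentation(v: LabeledVolume, params: AugmentParams) -> LabeledVolume:
    """Joint geometric + intensity augmentation (image trilinear, mask nearest)."""
    shape = v.image.shape
    idx = np.indices(shape).astype(float)
    ctr = (np.array(shape) - 1) / 2.0
    a = np.deg2rad(params.angle_deg)
    ca, sa = np.cos(a), np.sin(a)
    d0 = idx[0] - ctr[0]
    d1 = idx[1] - ctr[1]
    # in-plane rotation of the sampling grid (axes 0 and 1)
    src0 = ca * d0 - sa * d1 + ctr[0]
    src1 = sa * d0 + ca * d1 + ctr[1]
    coords = np.stack([src0, src1, idx[2]])
    if params.elastic_field is not None:
        coords = coords + params.elastic_field
    img = ndimage.map_coordinates(v.image.astype(np.float64), coords, order=1, mode="nearest")
    msk = ndimage.map_coordinates(v.mask, coords, order=0, mode="nearest")
    img = img * params.intensity_scale
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = ((img - lo) / (hi - lo)) ** params.gamma * (hi - lo) + lo
    return LabeledVolume(img.astype(np.float32), msk.astype(np.uint8), v.spacing_mm,
                         v.patient_id, list(v.lesions))


def augment(v: LabeledVolume, seed: int, elastic_amp_vox: float = 1.5,
            elastic_sigma_vox: float = 6.0) -> LabeledVolume:
    """Randomized augmentation: rotation (+-15 deg in-plane), elastic warp
    (amplitude/smoothness configurable, in voxels), intensity scale in
    [0.9, 1.1] and gamma in [0.8, 1.2]."""
    rng = np.random.default_rng(seed)
    return apply_augmentation(v, _sample_params(v.image.shape, rng, elastic_amp_vox,
                                                elastic_sigma_vox))


# ----------------------------------------------------------------------
# persistence
# ----------------------------------------------------------------------

def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_dataset(volumes, split: DatasetSplit, out_dir) -> pd.DataFrame:
    """Write NIfTI image/mask pairs plus a CSV manifest; returns the manifest."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for v in volumes:
        aff = _affine(v.spacing_mm)
        img_path = out / f"{v.patient_id}_image.nii.gz"
        msk_path = out / f"{v.patient_id}_mask.nii.gz"
        nib.save(nib.Nifti1Image(v.image.astype(np.float32), aff), img_path)
        nib.save(nib.Nifti1Image(v.mask.astype(np.uint8), aff), msk_path)
        rows.append(
            {
                "patient_id": v.patient_id,
                "split": split.split_of(v.patient_id),
                "class": v.patient_class,
                "image_path": str(img_path),
                "mask_path": str(msk_path),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def read_dataset(manifest_or_dir) -> list[LabeledVolume]:
    from pathlib import Path

    path = Path(manifest_or_dir)
    if path.is_dir():
        path = path / "manifest.csv"
    manifest = pd.read_csv(path)
    volumes = []
    for _, row in manifest.iterrows():
        img = nib.load(row["image_path"])
        msk = nib.load(row["mask_path"])
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        volumes.append(
            LabeledVolume(
                np.asarray(img.dataobj, dtype=np.float32),
                np.asarray(msk.dataobj, dtype=np.uint8),
                spacing,
                str(row["patient_id"]),
            )
        )
    return volumes
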