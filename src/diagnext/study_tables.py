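"""Published cohort composition of the kidney-CT study population.

The source study analyzed 3847 patients (12,446 CT slices) from a public
kidney CT collection.  The printed summary tables below are inputs to
the pipeline's bookkeeping checks: the volume-reconstruction table
(complete vs slice-interpolated volumes), the per-split patient/slice
distribution, and the pathology class distribution.  The functions
recompute the table's derived columns (fractions, ratios) from the raw
counts so the arithmetic can be verified and reused.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "volume_reconstruction_table",
    "split_distribution_table",
    "class_distribution_table",
    "interpolated_volume_fraction",
    "slices_per_patient",
    "cohort_class_proportions",
    "TOTAL_PATIENTS",
    "TOTAL_SLICES",
]

TOTAL_PATIENTS = 3847
TOTAL_SLICES = 12_446

# volume reconstruction summary: patients per volume type
_VOLUME_ROWS = [
    # (volume type, patients, mean slices, slice spacing mm)
    ("complete", 3215, 15.2, 3.0),
    ("interpolated", 632, 10.8, 2.5),
]

# per-split patient and slice counts
_SPLIT_ROWS = [
    # (split, patients, ct slices, patients with pathology)
    ("train", 2693, 8712, 1885),
    ("val", 577, 1867, 404),
    ("test", 577, 1867, 404),
]

# pathology class totals across the cohort
_CLASS_ROWS = [
    # (class, train, val, test)
    ("normal", 1014, 217, 217),
    ("cyst", 754, 162, 162),
    ("tumor", 446, 96, 96),
    ("stone", 275, 59, 59),
]


def volume_reconstruction_table() -> pd.DataFrame:
    df = pd.DataFrame(_VOLUME_ROWS, columns=["volume_type", "patients", "mean_slices",
                                             "slice_spacing_mm"])
    df["patient_fraction_pct"] = 100.0 * df["patients"] / df["patients"].sum()
    return df


def split_distribution_table() -> pd.DataFrame:
    df = pd.DataFrame(_SPLIT_ROWS, columns=["split", "patients", "slices",
                                            "patients_with_pathology"])
    df["slices_per_patient"] = df["slices"] / df["patients"]
    df["pathology_fraction_pct"] = 100.0 * df["patients_with_pathology"] / df["patients"]
    return df


def class_distribution_table() -> pd.DataFrame:
    df = pd.DataFrame(_CLASS_ROWS, columns=["class", "train", "val", "test"])
    df["total"] = df[["train", "val", "test"]].sum(axis=1)
    return df


def interpolated_volume_fraction() -> float:
    """Percentage of patient volumes built with slice interpolation."""
    df = volume_reconstruction_table().set_index("volume_type")
    return float(df.loc["interpolated", "patient_fraction_pct"])


def slices_per_patient(split: str | None = None) -> float:
    """Mean CT slices per patient, overall or for one split."""
    df = split_distribution_table().set_index("split")
    if split is None:
        return float(df["slices"].sum() / df["patients"].sum())
    return float(df.loc[split, "slices_per_patient"])


def cohort_class_proportions() -> dict[str, float]:
    """Pathology class proportions of the cohort (phantom class-mix source)."""
    df = class_distribution_table()
    total = df["total"].sum()
    return {row["class"]: row["total"] / total for _, row in df.iterrows()}
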