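"""Readers and writers: header-keyed CSV tables, NIfTI volume/mask pairs,
and structured-text (YAML) reports."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .cohort import (LESION_COLUMNS, PATIENT_COLUMNS, CohortTable,
                     validate_feature_table)
from .errors import ValidationError
from .similarity import SilhouetteResult


def read_cohort(directory: str | Path) -> CohortTable:
    """Read ``patients.csv`` and ``lesions.csv`` from a directory.  Columns
    are header-keyed, so order does not matter; validation names the
    offending row and column."""
    directory = Path(directory)
    for name in ("patients.csv", "lesions.csv"):
        if not (directory / name).exists():
            raise ValidationError(f"missing file {directory / name}")
    patients = pd.read_csv(directory / "patients.csv")
    lesions = pd.read_csv(directory / "lesions.csv")
    return CohortTable(patients, lesions)


def write_cohort_tables(cohort: CohortTable, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cohort.patients[PATIENT_COLUMNS].to_csv(directory / "patients.csv",
                                            index=False)
    cohort.lesions[LESION_COLUMNS].to_csv(directory / "lesions.csv",
                                          index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    """Read and validate a lesions x features table."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"missing file {path}")
    table = pd.read_csv(path)
    validate_feature_table(table)
    return table


def write_features(table: pd.DataFrame, path: str | Path) -> None:
    validate_feature_table(table)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def read_volume(path: str | Path) -> tuple[np.ndarray, float]:
    """Load a NIfTI volume; returns the array and its (isotropic) voxel
    spacing in mm."""
    img = nib.load(str(path))
    spacing = img.header.get_zooms()[:3]
    if not np.allclose(spacing, spacing[0]):
        raise ValidationError(f"{path}: anisotropic spacing {spacing}")
    return np.asarray(img.dataobj, dtype=float), float(spacing[0])


def write_volume(array: np.ndarray, spacing_mm: float,
                 path: str | Path) -> None:
    affine = np.diag([spacing_mm, spacing_mm, spacing_mm, 1.0])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(array), affine), str(path))


def silhouette_report(result: SilhouetteResult) -> dict:
    """Serializable report of one slicing: per-lesion values, per-patient
    means with excluded flags, and the cohort mean."""
    return {
        "slicing": result.slicing,
        "mean_index": None if np.isnan(result.mean_index)
        else float(result.mean_index),
        "per_patient": {
            str(pid): {"value": float(row["value"]),
                       "n_lesions": int(row["n_lesions"]),
                       "excluded": bool(row["excluded"])}
            for pid, row in result.per_patient.iterrows()},
        "per_lesion": {str(lid): float(v)
                       for lid, v in result.per_lesion.items()},
    }


def write_report(payload: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_report(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
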