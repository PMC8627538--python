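"""Cohort data model: patient and lesion tables, and the lesions x features table.

The pipeline's central exchange object is the *feature table*: a pandas
DataFrame with one row per lesion, the metadata columns ``lesion_id``,
``patient_id``, ``site_class``, ``suv_max``, and one numeric column per
radiomic feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Closed vocabulary of anatomical site classes (TNM-derived): regional lymph
#: node, distant lymph node, bone metastasis.
SITE_CLASSES = ("REGIONAL_LN", "DISTANT_LN", "BONE")

ADT_STATES = ("ON", "OFF")
TREATMENTS = ("RP", "RP+RT", "RT", "OTHER")

PATIENT_COLUMNS = ["patient_id", "age", "gleason", "psa_ng_ml", "adt_status",
                   "primary_treatment"]
LESION_COLUMNS = ["lesion_id", "patient_id", "site_class", "suv_max"]

#: Metadata columns of a feature table; every other column is a feature.
METADATA_COLUMNS = LESION_COLUMNS


@dataclass
class CohortTable:
    """Per-patient clinical records plus per-lesion rows.

    Parameters
    ----------
    patients : DataFrame with columns ``PATIENT_COLUMNS``.
    lesions : DataFrame with columns ``LESION_COLUMNS``.
    """

    patients: pd.DataFrame
    lesions: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for col in PATIENT_COLUMNS:
            if col not in self.patients.columns:
                raise ValidationError(f"patient table missing column {col!r}")
        for col in LESION_COLUMNS:
            if col not in self.lesions.columns:
                raise ValidationError(f"lesion table missing column {col!r}")
        if self.patients["patient_id"].duplicated().any():
            dup = self.patients.loc[self.patients["patient_id"].duplicated(),
                                    "patient_id"].iloc[0]
            raise ValidationError(f"duplicate patient_id {dup!r}")
        known = set(self.patients["patient_id"])
        for idx, row in self.lesions.iterrows():
            if row["patient_id"] not in known:
                raise ValidationError(
                    f"lesion row {idx} (lesion_id={row['lesion_id']!r}): "
                    f"unknown patient_id {row['patient_id']!r}")
            if row["site_class"] not in SITE_CLASSES:
                raise ValidationError(
                    f"lesion row {idx} (lesion_id={row['lesion_id']!r}): "
                    f"site_class {row['site_class']!r} not in {SITE_CLASSES}")
        bad_psa = self.patients["psa_ng_ml"] < 0
        if bad_psa.any():
            idx = int(np.flatnonzero(bad_psa)[0])
            raise ValidationError(f"patient row {idx}: negative psa_ng_ml")
        bad_adt = ~self.patients["adt_status"].isin(ADT_STATES)
        if bad_adt.any():
            idx = int(np.flatnonzero(bad_adt)[0])
            raise ValidationError(
                f"patient row {idx}: adt_status must be one of {ADT_STATES}")

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_lesions(self) -> int:
        return len(self.lesions)

    def lesion_counts(self) -> pd.Series:
        """Lesions per patient, indexed by patient_id (patients with zero
        lesions are absent)."""
        return self.lesions.groupby("patient_id").size()


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the feature columns of a feature table (everything that is
    not lesion metadata)."""
    return [c for c in table.columns if c not in METADATA_COLUMNS]


def validate_feature_table(table: pd.DataFrame) -> None:
    for col in ("lesion_id", "patient_id"):
        if col not in table.columns:
            raise ValidationError(f"feature table missing column {col!r}")
    if table["lesion_id"].duplicated().any():
        dup = table.loc[table["lesion_id"].duplicated(), "lesion_id"].iloc[0]
        raise ValidationError(f"duplicate lesion_id {dup!r}")
    feats = feature_columns(table)
    if not feats:
        raise ValidationError("feature table has no feature columns")
    nonnum = [c for c in feats
              if not np.issubdtype(table[c].dtype, np.number)]
    if nonnum:
        raise ValidationError(f"non-numeric feature columns: {nonnum}")
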