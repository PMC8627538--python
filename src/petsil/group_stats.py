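"""Tumor-burden classification and nonparametric group testing.

Burden: a patient is *oligometastatic* when their lesion count is at or
below a threshold (3 or 5 lesions — the field's two common definitions),
otherwise *plurimetastatic*; a three-way class separates counts between the
two thresholds.  Both the inclusive (``n <= t``) and exclusive (``n < t``)
boundary conventions are available.

Tests: two-tailed Mann–Whitney per radiomic feature across a clinical split
(burden, Gleason <=7 vs >7, median-PSA, ADT on/off, site contrasts), the
same test for PSA, and Kruskal–Wallis on per-patient silhouette means.
Default significance levels follow the screening convention alpha = 0.01
for the Gleason split and 0.001 otherwise; PSA uses 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, feature_columns
from .errors import SplitError, ValidationError
from .similarity import SilhouetteResult

OLIGO, PLURI = "OLIGO", "PLURI"
THREE_WAY = ("OLIGO3", "INTERMEDIATE", "PLURI5")


def classify_burden(lesion_counts: pd.Series,
                    inclusive: bool = True) -> pd.DataFrame:
    """Classify patients under the 3- and 5-lesion thresholds.

    ``inclusive`` (default): OLIGO iff ``n <= threshold``; exclusive:
    OLIGO iff ``n < threshold``.  Returns a DataFrame indexed by patient id
    with ``n_lesions``, ``class3``, ``class5`` and the derived
    ``class3way``.
    """
    counts = pd.Series(lesion_counts).astype(int)
    if (counts < 1).any():
        bad = counts.index[counts < 1][0]
        raise ValidationError(f"patient {bad!r}: lesion count must be >= 1")

    def oligo(n: int, t: int) -> bool:
        return n <= t if inclusive else n < t

    rows = {}
    for pid, n in counts.items():
        c3 = OLIGO if oligo(n, 3) else PLURI
        c5 = OLIGO if oligo(n, 5) else PLURI
        if c3 == OLIGO:
            c3w = "OLIGO3"
        elif c5 == OLIGO:
            c3w = "INTERMEDIATE"
        else:
            c3w = "PLURI5"
        rows[pid] = {"n_lesions": int(n), "class3": c3, "class5": c5,
                     "class3way": c3w}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "patient_id"
    return out


@dataclass
class ClinicalSplit:
    """A named partition of patients (or lesions) into groups."""

    name: str
    assignment: pd.Series  # patient_id (or lesion_id) -> group label
    level: str = "patient"

    def __post_init__(self) -> None:
        counts = self.assignment.value_counts()
        if len(counts) < 2:
            raise SplitError(f"split {self.name}: fewer than 2 groups")
        if (counts == 0).any():
            raise SplitError(f"split {self.name}: empty group")


def make_split(name: str, cohort: CohortTable,
               burden: pd.DataFrame | None = None,
               inclusive: bool = True) -> ClinicalSplit:
    """Build one of the pre-specified clinical splits.

    ``BURDEN3``/``BURDEN5``/``BURDEN3WAY`` (lesion-count classes),
    ``GLEASON`` (<=7 vs >7), ``PSA_MEDIAN`` (at/below vs above the cohort's
    own median), ``ADT`` (on vs off) — all patient-level; ``SITE`` is
    lesion-level (site classes).
    """
    pats = cohort.patients.set_index("patient_id")
    if name in ("BURDEN3", "BURDEN5", "BURDEN3WAY"):
        if burden is None:
            burden = classify_burden(cohort.lesion_counts(), inclusive)
        col = {"BURDEN3": "class3", "BURDEN5": "class5",
               "BURDEN3WAY": "class3way"}[name]
        assignment = burden[col]
    elif name == "GLEASON":
        assignment = pd.Series(
            np.where(pats["gleason"] <= 7, "GS<=7", "GS>7"), index=pats.index)
    elif name == "PSA_MEDIAN":
        med = pats["psa_ng_ml"].median()
        assignment = pd.Series(
            np.where(pats["psa_ng_ml"] <= med, "PSA_low", "PSA_high"),
            index=pats.index)
    elif name == "ADT":
        assignment = pats["adt_status"]
    elif name == "SITE":
        assignment = cohort.lesions.set_index("lesion_id")["site_class"]
        return ClinicalSplit(name, assignment, level="lesion")
    else:
        raise SplitError(f"unknown split name {name!r}")
    return ClinicalSplit(name, assignment.rename("group"), level="patient")


_SITE_PRIORITY = ("BONE", "DISTANT_LN", "REGIONAL_LN")


def patient_site_split(cohort: CohortTable) -> ClinicalSplit:
    """Patient-level site contrast: each patient is labelled by their
    dominant lesion site (ties broken toward the more distant class,
    bone > distant LN > regional LN)."""
    def dominant(sites: pd.Series) -> str:
        counts = sites.value_counts()
        best = counts.max()
        for s in _SITE_PRIORITY:
            if counts.get(s, 0) == best:
                return s
        return counts.idxmax()

    assignment = cohort.lesions.groupby("patient_id")["site_class"].apply(dominant)
    return ClinicalSplit("SITE_DOMINANT", assignment.rename("group"))


def default_alpha(split_name: str) -> float:
    """Screening significance level: 0.01 for the Gleason split, 0.001 for
    every other clinical category."""
    return 0.01 if split_name.upper().startswith("GLEASON") else 0.001


def univariate_screen(features: pd.DataFrame, split: ClinicalSplit,
                      alpha: float | None = None,
                      level: str = "lesion",
                      benjamini_hochberg: bool = False) -> pd.DataFrame:
    """Two-tailed Mann–Whitney test of every feature across a two-group
    split.

    ``level="lesion"`` (default) compares lesion rows labelled by their
    patient's group; ``level="patient"`` compares per-patient medians.
    Returns one row per feature: U statistic, two-sided p and a
    ``significant`` flag at ``alpha`` (default per :func:`default_alpha`);
    an optional Benjamini–Hochberg adjusted-p column can be added.
    """
    alpha = default_alpha(split.name) if alpha is None else alpha
    cols = feature_columns(features)
    if split.level == "lesion":
        groups = features["lesion_id"].map(split.assignment)
    else:
        groups = features["patient_id"].map(split.assignment)
    data = features.assign(_group=groups.values)
    if data["_group"].isna().any():
        missing = data.loc[data["_group"].isna(), "lesion_id"].tolist()
        raise SplitError(f"split {split.name}: no group for lesions {missing}")
    if level == "patient":
        data = (data.groupby(["patient_id", "_group"], as_index=False)[cols]
                .median())
    labels = data["_group"].unique()
    if len(labels) != 2:
        raise SplitError(f"split {split.name}: screen needs exactly 2 groups,"
                         f" got {sorted(map(str, labels))}")
    g1 = data[data["_group"] == labels[0]]
    g2 = data[data["_group"] == labels[1]]
    if g1.empty or g2.empty:
        raise SplitError(f"split {split.name}: empty group")
    rows = []
    for c in cols:
        u, p = stats.mannwhitneyu(g1[c], g2[c], alternative="two-sided")
        rows.append({"feature": c, "U": float(u), "p": float(p),
                     "significant": bool(p <= alpha)})
    out = pd.DataFrame(rows)
    if benjamini_hochberg:
        out["p_bh"] = stats.false_discovery_control(out["p"], method="bh")
    return out


@dataclass
class GroupTestResult:
    statistic: float
    p: float
    group_sizes: dict
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return bool(self.p <= self.alpha)


def psa_test(psa: pd.Series, split: ClinicalSplit,
             alpha: float = 0.05):
    """Compare PSA distributions across a split.

    Two groups: a single two-sided Mann–Whitney (:class:`GroupTestResult`).
    Three or more groups (e.g., the skeleton / regional / distant site
    contrast): pairwise Mann–Whitney tests, returned as a DataFrame.
    """
    groups = psa.index.map(split.assignment)
    if pd.isna(groups).any():
        raise SplitError(f"split {split.name}: patients without a group")
    by = {g: psa[groups == g].to_numpy() for g in pd.unique(groups)}
    if any(len(v) == 0 for v in by.values()) or len(by) < 2:
        raise SplitError(f"split {split.name}: empty group")
    if len(by) == 2:
        (ga, xa), (gb, xb) = by.items()
        u, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        return GroupTestResult(float(u), float(p),
                               {ga: len(xa), gb: len(xb)}, alpha)
    rows = []
    names = sorted(by)
    for i, ga in enumerate(names):
        for gb in names[i + 1:]:
            u, p = stats.mannwhitneyu(by[ga], by[gb],
                                      alternative="two-sided")
            rows.append({"group1": ga, "group2": gb, "U": float(u),
                         "p": float(p), "significant": bool(p <= alpha)})
    return pd.DataFrame(rows)


def silhouette_group_test(result: SilhouetteResult, split: ClinicalSplit,
                          alpha: float = 0.05) -> GroupTestResult:
    """Kruskal–Wallis test of per-patient silhouette means across groups,
    after removing excluded (single-lesion) patients.  Tie-corrected H,
    chi-square p with ``df = groups - 1``."""
    pp = result.per_patient
    kept = pp[~pp["excluded"]]
    groups = kept.index.map(split.assignment)
    if pd.isna(groups).any():
        raise SplitError(f"split {split.name}: patients without a group")
    samples = {g: kept.loc[groups == g, "value"].to_numpy()
               for g in pd.unique(split.assignment)}
    empty = [g for g, v in samples.items() if len(v) == 0]
    if empty:
        raise SplitError(f"split {split.name}: groups {empty} empty after "
                         "excluding single-lesion patients")
    if len(samples) < 2:
        raise SplitError(f"split {split.name}: fewer than 2 groups")
    h, p = stats.kruskal(*samples.values())
    return GroupTestResult(float(h), float(p),
                           {g: len(v) for g, v in samples.items()}, alpha)
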