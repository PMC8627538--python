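"""Intra-patient lesion similarity via silhouette indices.

Lesions are embedded in a standardized feature space (z-score per feature,
optionally followed by PCA) and each lesion receives a silhouette value with
*patients as clusters*: ``s = (b - a) / max(a, b)`` where ``a`` is the mean
Euclidean distance to the patient's other lesions and ``b`` the smallest mean
distance to any other patient's lesions.  ``s`` near 1 means a patient's
lesions are tightly matched to each other; negative ``s`` means they sit
closer to other patients' lesions than to their own.

Three slicings are supported: patient-based over all lesions (ALL),
anatomy-based (restricted to one site class) and metabolism-based
(restricted to one SUVmax tertile); restricted slicings re-embed on their
subset.  Patients with a single lesion in the analysis set get the
conventional value 0 and are excluded from cohort means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy import stats

from .cohort import feature_columns
from .errors import (EmbeddingDegenerateError, SilhouetteUndefinedError,
                     TestUndefinedError)


@dataclass
class EmbeddedTable:
    """Lesions embedded in the standardized analysis space."""

    coordinates: np.ndarray
    lesion_ids: list[str]
    patient_ids: list[str]
    center: np.ndarray
    scale: np.ndarray
    dropped: list[str]
    method: str


def embed(features: pd.DataFrame, method: str = "ZSCORE",
          n_components: int | None = None,
          columns: list[str] | None = None) -> EmbeddedTable:
    """Z-score each feature over all lesions (zero-variance features are
    dropped and listed, never divided by zero); ``method="ZSCORE_PCA"``
    additionally projects onto the leading principal axes
    (``n_components`` axes, or enough to retain 90% variance)."""
    if len(features) < 2:
        raise EmbeddingDegenerateError("need >= 2 lesions to embed")
    cols = columns if columns is not None else feature_columns(features)
    X = features[cols].to_numpy(dtype=float)
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    keep = scale > 0
    if not keep.any():
        raise EmbeddingDegenerateError("all features are constant")
    dropped = [c for c, k in zip(cols, keep) if not k]
    Z = (X[:, keep] - center[keep]) / scale[keep]
    if method.upper() == "ZSCORE_PCA":
        from sklearn.decomposition import PCA
        nc = n_components if n_components is not None else 0.9
        nc = min(nc, min(Z.shape)) if isinstance(nc, int) else nc
        Z = PCA(n_components=nc, svd_solver="full").fit_transform(Z)
    elif method.upper() != "ZSCORE":
        raise ValueError(f"unknown embedding method {method!r}")
    return EmbeddedTable(coordinates=Z,
                         lesion_ids=list(features["lesion_id"]),
                         patient_ids=list(features["patient_id"]),
                         center=center[keep], scale=scale[keep],
                         dropped=dropped, method=method.upper())


def lesion_silhouettes(coordinates: np.ndarray, labels: np.ndarray,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Per-lesion silhouette values with the given cluster labels
    (typically patient ids).

    Returns ``(s, excluded)``: lesions in singleton clusters get ``s = 0``
    and ``excluded = True`` (they still serve as neighbour clusters for the
    others).  Requires at least two distinct labels.
    """
    labels = np.asarray(labels)
    X = np.asarray(coordinates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    uniq, inv = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        raise SilhouetteUndefinedError("need >= 2 distinct patient labels")
    n, G = len(labels), uniq.size
    D = cdist(X, X)
    ind = np.zeros((n, G))
    ind[np.arange(n), inv] = 1.0
    counts = ind.sum(axis=0)
    sums = D @ ind  # sums[i, g] = total distance from lesion i to group g
    own = counts[inv]
    excluded = own < 2
    a = np.zeros(n)
    a[~excluded] = sums[np.arange(n), inv][~excluded] / (own[~excluded] - 1)
    mean_other = sums / counts[None, :]
    mean_other[np.arange(n), inv] = np.inf
    b = mean_other.min(axis=1)
    s = np.zeros(n)
    denom = np.maximum(a, b)
    ok = (~excluded) & (denom > 0)
    s[ok] = (b[ok] - a[ok]) / denom[ok]
    return s, excluded


@dataclass
class SilhouetteResult:
    """Per-lesion and per-patient silhouette values under one slicing.

    ``per_patient`` has one row per patient present in the analysis subset
    (columns ``value``, ``n_lesions``, ``excluded``); ``mean_index`` averages
    the non-excluded patients.
    """

    per_lesion: pd.Series
    per_patient: pd.DataFrame
    slicing: str
    mean_index: float


def patient_silhouette(per_lesion: np.ndarray, excluded: np.ndarray,
                       patient_ids: list[str]) -> tuple[pd.DataFrame, float]:
    """Aggregate lesion silhouettes to per-patient means and the cohort
    mean over non-excluded (multi-lesion) patients."""
    df = pd.DataFrame({"patient_id": patient_ids, "s": per_lesion,
                       "excluded": excluded})
    rows = {}
    for pid, grp in df.groupby("patient_id", sort=True):
        exc = bool(grp["excluded"].all())
        value = 0.0 if exc else float(grp.loc[~grp["excluded"], "s"].mean())
        rows[pid] = {"value": value, "n_lesions": len(grp), "excluded": exc}
    per_patient = pd.DataFrame.from_dict(rows, orient="index")
    per_patient.index.name = "patient_id"
    kept = per_patient.loc[~per_patient["excluded"], "value"]
    mean_index = float(kept.mean()) if len(kept) else float("nan")
    return per_patient, mean_index


def _result_from_subset(subset: pd.DataFrame, slicing: str,
                        method: str = "ZSCORE",
                        n_components: int | None = None) -> SilhouetteResult:
    if subset["patient_id"].nunique() < 2:
        raise SilhouetteUndefinedError(
            f"slicing {slicing}: fewer than 2 patients in subset")
    emb = embed(subset, method=method, n_components=n_components)
    s, exc = lesion_silhouettes(emb.coordinates, np.array(emb.patient_ids))
    per_lesion = pd.Series(s, index=emb.lesion_ids, name="silhouette")
    per_patient, mean_index = patient_silhouette(s, exc, emb.patient_ids)
    return SilhouetteResult(per_lesion=per_lesion, per_patient=per_patient,
                            slicing=slicing, mean_index=mean_index)


def patient_based(features: pd.DataFrame, method: str = "ZSCORE",
                  n_components: int | None = None) -> SilhouetteResult:
    """Patient-based analysis: silhouettes over all lesions."""
    return _result_from_subset(features, "ALL", method, n_components)


def anatomy_silhouette(features: pd.DataFrame, site: str,
                       method: str = "ZSCORE",
                       n_components: int | None = None) -> SilhouetteResult:
    """Anatomy-based analysis: restrict to one site class, re-embed on the
    subset, recompute silhouettes with patients as labels."""
    subset = features[features["site_class"] == site]
    if subset.empty:
        raise SilhouetteUndefinedError(f"no lesions with site {site!r}")
    return _result_from_subset(subset, f"SITE({site})", method, n_components)


def suv_tertiles(suv_max: pd.Series) -> pd.Series:
    """Assign each lesion to a SUVmax tertile (1|2|3).

    Boundaries are the inclusive empirical 1/3 and 2/3 quantiles of the
    whole cohort's SUVmax; lesions exactly at a boundary go to the lower
    tertile (deterministic, order-independent).
    """
    q1, q2 = np.quantile(suv_max.to_numpy(dtype=float), [1 / 3, 2 / 3])
    return pd.Series(1 + (suv_max > q1).astype(int) + (suv_max > q2).astype(int),
                     index=suv_max.index, name="tertile")


def metabolism_silhouette(features: pd.DataFrame, tertile: int,
                          method: str = "ZSCORE",
                          n_components: int | None = None) -> SilhouetteResult:
    """Metabolism-based analysis: restrict to one SUVmax tertile (boundaries
    from the whole cohort), re-embed, recompute."""
    if tertile not in (1, 2, 3):
        raise ValueError("tertile must be 1, 2 or 3")
    tert = suv_tertiles(features["suv_max"])
    subset = features[tert == tertile]
    if subset.empty:
        raise SilhouetteUndefinedError(f"tertile {tertile} is empty")
    return _result_from_subset(subset, f"TERTILE({tertile})", method,
                               n_components)


@dataclass
class PairedTestResult:
    """Classical paired t-test on per-patient silhouette means."""

    t: float
    p: float
    n: int
    mean_difference: float
    degenerate: bool = False


def paired_slicing_test(all_result: SilhouetteResult,
                        restricted_result: SilhouetteResult,
                        ) -> PairedTestResult:
    """Two-sided paired t-test comparing per-patient means between two
    slicings; pairing key is the patient id, over patients non-excluded in
    both.  All-zero differences give ``t = 0, p = 1``; constant nonzero
    differences are degenerate (``p = NaN`` with flag)."""
    a = all_result.per_patient
    b = restricted_result.per_patient
    common = a.index[~a["excluded"]].intersection(b.index[~b["excluded"]])
    n = len(common)
    if n < 2:
        raise TestUndefinedError("fewer than 2 paired non-excluded patients")
    d = (b.loc[common, "value"] - a.loc[common, "value"]).to_numpy()
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            return PairedTestResult(t=0.0, p=1.0, n=n, mean_difference=0.0)
        return PairedTestResult(t=float("nan"), p=float("nan"), n=n,
                                mean_difference=float(d.mean()),
                                degenerate=True)
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2 * stats.t.sf(abs(t), df=n - 1))
    return PairedTestResult(t=t, p=p, n=n, mean_difference=float(d.mean()))
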