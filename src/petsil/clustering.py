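"""Unsupervised clustering of lesions in the embedded space.

k-means with seeded restarts over a range of cluster counts; the reported
solution maximizes the mean silhouette over the range (an explicit,
reproducible stand-in for "best interpretable" model selection).  Clusters
are then characterized by their composition over SUVmax tertiles, burden
classes and anatomical sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.metrics import silhouette_score

from .errors import PetsilError
from .similarity import EmbeddedTable


@dataclass
class ClusterSolution:
    """A clustering of lesions with its model-selection trace."""

    k: int
    labels: pd.Series  # lesion_id -> cluster id in 1..k
    selection_scores: dict[int, float]  # k -> mean silhouette
    chosen_k: int
    degenerate: bool = False


def cluster_lesions(space: EmbeddedTable, k_range=range(2, 6),
                    seed: int = 0, n_restarts: int = 20,
                    method: str = "kmeans") -> ClusterSolution:
    """Cluster lesions for each k in ``k_range`` and keep the k with the
    highest mean silhouette.

    ``method`` is ``"kmeans"`` (default; ``n_restarts`` seeded restarts per
    k) or ``"ward"`` (agglomerative).  Identical duplicated points only
    (zero total variance) yield a degenerate single-cluster solution with a
    flag rather than an arbitrary split.
    """
    X = np.asarray(space.coordinates, dtype=float)
    n = len(X)
    k_range = [int(k) for k in k_range]
    if not k_range or min(k_range) < 2 or max(k_range) > n - 1:
        raise PetsilError(f"k_range must lie within 2..{n - 1}")
    if np.allclose(X, X[0]):
        labels = pd.Series(np.ones(n, dtype=int), index=space.lesion_ids)
        return ClusterSolution(k=1, labels=labels, selection_scores={},
                               chosen_k=1, degenerate=True)
    scores: dict[int, float] = {}
    fits: dict[int, np.ndarray] = {}
    for k in k_range:
        if method == "kmeans":
            model = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        elif method == "ward":
            model = AgglomerativeClustering(n_clusters=k, linkage="ward")
        else:
            raise PetsilError(f"unknown clustering method {method!r}")
        lab = model.fit_predict(X)
        fits[k] = lab
        scores[k] = float(silhouette_score(X, lab))
    chosen = max(k_range, key=lambda k: scores[k])
    labels = pd.Series(fits[chosen] + 1, index=space.lesion_ids,
                       name="cluster")
    return ClusterSolution(k=chosen, labels=labels, selection_scores=scores,
                           chosen_k=chosen)


@dataclass
class ClusterProfile:
    """Per-cluster composition over categorical lesion metadata.

    ``proportions[category]`` is a clusters x levels table whose rows sum
    to 1; ``enrichment[category]`` flags cells whose proportion exceeds the
    cohort-wide proportion; ``chi2_p[category]`` is a descriptive
    chi-square test of the cluster x level contingency table.
    """

    proportions: dict[str, pd.DataFrame]
    enrichment: dict[str, pd.DataFrame]
    chi2_p: dict[str, float]


def characterize(solution: ClusterSolution,
                 metadata: pd.DataFrame) -> ClusterProfile:
    """Profile each cluster by the categorical columns of ``metadata``
    (indexed by lesion id; e.g. site class, SUVmax tertile, burden class)."""
    missing = [lid for lid in solution.labels.index
               if lid not in metadata.index]
    if missing:
        raise PetsilError(f"metadata missing for lesions: {missing}")
    meta = metadata.loc[solution.labels.index]
    proportions, enrichment, chi2_p = {}, {}, {}
    for col in meta.columns:
        table = pd.crosstab(solution.labels, meta[col])
        props = table.div(table.sum(axis=1), axis=0)
        cohort = meta[col].value_counts(normalize=True).reindex(props.columns)
        proportions[col] = props
        enrichment[col] = props.gt(cohort, axis=1)
        if table.shape[0] > 1 and table.shape[1] > 1:
            chi2_p[col] = float(stats.chi2_contingency(table.to_numpy())[1])
        else:
            chi2_p[col] = float("nan")
    return ClusterProfile(proportions=proportions, enrichment=enrichment,
                          chi2_p=chi2_p)
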