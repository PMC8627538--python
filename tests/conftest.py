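"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from petsil.synthetic import SyntheticConfig, generate_feature_cohort


def brute_silhouette(X: np.ndarray, labels) -> tuple[np.ndarray, np.ndarray]:
    """O(n^2) loop silhouette: the reference the vectorized implementation
    must match exactly.  Singleton-cluster points get (0, excluded)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    n = len(labels)
    s = np.zeros(n)
    excluded = np.zeros(n, dtype=bool)
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            excluded[i] = True
            continue
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in own])
        b = np.inf
        for lab in set(labels) - {labels[i]}:
            other = [j for j in range(n) if labels[j] == lab]
            b = min(b, np.mean([np.linalg.norm(X[i] - X[j]) for j in other]))
        denom = max(a, b)
        s[i] = (b - a) / denom if denom > 0 else 0.0
    return s, excluded


def random_cohort_frame(rng: np.random.Generator, n_patients: int = 6,
                        max_lesions: int = 4, d: int = 3) -> pd.DataFrame:
    """Small random feature table with metadata columns."""
    rows = []
    for ip in range(n_patients):
        pid = f"P{ip:02d}"
        for il in range(rng.integers(1, max_lesions + 1)):
            rows.append({"lesion_id": f"{pid}_L{il}", "patient_id": pid,
                         "site_class": "BONE",
                         "suv_max": float(rng.lognormal(1.5, 0.4))})
    df = pd.DataFrame(rows)
    feats = rng.normal(size=(len(df), d))
    for k in range(d):
        df[f"f{k}"] = feats[:, k]
    return df


@pytest.fixture
def small_cohort():
    """10-patient feature-mode cohort with private archetypes."""
    cfg = SyntheticConfig(n_patients=10, n_archetypes=10, seed=42,
                          lesion_count_law={1: 0.2, 2: 0.3, 3: 0.3, 4: 0.2})
    return generate_feature_cohort(cfg)


@pytest.fixture
def cohesive_cohort():
    """Cohort with tight within-patient clusters (positive silhouettes)."""
    cfg = SyntheticConfig(n_patients=12, n_archetypes=12, sigma_within=0.1,
                          sigma_between=1.0, site_effect_scale=0.0,
                          lesion_count_law={2: 0.5, 3: 0.5}, seed=7)
    return generate_feature_cohort(cfg)
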