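"""Exercise-class clustering from combined sEMG + IMU features.

Trials are clustered with k-means (multiple restarts) on z-scored
feature columns; k defaults to the number of protocol × rep-count
classes (2 × 3 = 6).  Recovery of the true class labels is scored with
the adjusted Rand index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .io import ALL_FEATURES, IMU_FEATURES

__all__ = [
    "ClusterResult",
    "standardize_features",
    "cluster_trials",
    "adjusted_rand",
    "DEFAULT_K",
]

DEFAULT_K = 6  # 2 protocols × {3, 6, 9} reps


@dataclass
class ClusterResult:
    assignments: np.ndarray
    k: int
    centroid_table: pd.DataFrame  # k × features, standardized units
    inertia: float
    ari: float | None = None


def standardize_features(
    table: pd.DataFrame, feature_subset: Sequence[str] | None = None
) -> pd.DataFrame:
    """Z-score feature columns of a wide per-trial table.

    Zero-variance columns are dropped with a warning rather than
    producing NaNs.
    """
    features = list(feature_subset) if feature_subset is not None else list(ALL_FEATURES)
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    if len(table) < 2:
        raise ValueError("need at least 2 trials to standardize")
    X = table[features].astype(float)
    sd = X.std(ddof=0)
    dead = sd[sd == 0].index.tolist()
    if dead:
        warnings.warn(f"dropping zero-variance features: {dead}")
        X = X.drop(columns=dead)
        sd = sd.drop(index=dead)
    if X.shape[1] == 0:
        raise ValueError("no features with nonzero variance")
    return (X - X.mean()) / sd


def cluster_trials(
    z: pd.DataFrame | np.ndarray, k: int = DEFAULT_K, n_restarts: int = 10, seed: int = 0
) -> ClusterResult:
    """Centroid-based partition minimizing within-cluster squared distance."""
    X = z.to_numpy() if isinstance(z, pd.DataFrame) else np.asarray(z, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if X.shape[0] < k:
        raise ValueError(f"k={k} exceeds the {X.shape[0]} available trials")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(X)
    cols = list(z.columns) if isinstance(z, pd.DataFrame) else None
    centroids = pd.DataFrame(km.cluster_centers_, columns=cols)
    return ClusterResult(
        assignments=labels, k=k, centroid_table=centroids, inertia=float(km.inertia_)
    )


def adjusted_rand(assignments: Sequence, truth: Sequence) -> float:
    """Chance-corrected, permutation-invariant partition agreement."""
    a = np.asarray(assignments)
    b = np.asarray(truth)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(adjusted_rand_score(b, a))
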