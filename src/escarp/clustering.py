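"""Landscape-composition typology by k-means on standardized metrics.

Workflow: z-score the composition features (PRD, SHDI, PLAND_1-6, sample
standard deviation), run k-means with multiple restarts, screen candidate
k with internal validity indices (mean silhouette, Dunn, Calinski-
Harabasz) plus repeat-run consistency (mean pairwise adjusted Rand index
over reseeded runs), and diagnose spatial autocorrelation of the labels
with per-cluster Moran's I on a one-vs-rest indicator.  Moran's I is
diagnostic only and never feeds back into the clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from sklearn.cluster import KMeans
from sklearn.metrics import (
    adjusted_rand_score,
    calinski_harabasz_score,
    silhouette_score,
)

from .metrics import COMPOSITION_FEATURES


def zscore(table: pd.DataFrame, features: list[str] | None = None
           ) -> tuple[np.ndarray, pd.DataFrame]:
    """Standardize features to zero mean / unit (sample, ddof=1) sd.

    Returns the z-matrix and a parameter table (feature, mean, sd) that
    reproduces ``z = (x - mean) / sd``.  A zero-variance feature is an
    error naming the feature (never silently dropped).
    """
    features = list(features or COMPOSITION_FEATURES)
    X = table[features].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        bad = [f for f in features if not np.isfinite(table[f]).all()]
        raise ValueError(f"non-finite values in features {bad}")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = [f for f, s in zip(features, sd) if s == 0]
    if zero:
        raise ValueError(f"zero-variance feature(s): {zero}")
    params = pd.DataFrame({"feature": features, "mean": mean, "sd": sd})
    return (X - mean) / sd, params


@dataclass
class ClusterModel:
    """Fitted k-means typology (labels are 1-based)."""

    feature_names: list[str]
    standardization: pd.DataFrame     # feature, mean, sd
    k: int
    centroids: np.ndarray             # k x p, z-space
    labels: np.ndarray                # 1..k per unit, aligned to input rows
    inertia: float
    n_init: int
    seed: int


def kmeans_cluster(Z: np.ndarray, k: int, n_init: int = 25, seed: int = 0
                   ) -> tuple[np.ndarray, np.ndarray, float]:
    """K-means (Euclidean, Lloyd) with n_init restarts; labels in 1..k."""
    Z = np.asarray(Z, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k >= len(Z):
        raise ValueError(f"k={k} must be < number of units {len(Z)}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed,
                algorithm="lloyd").fit(Z)
    labels = km.labels_ + 1
    if len(np.unique(labels)) < k:
        raise RuntimeError(f"k-means produced an empty cluster at k={k}")
    return labels, km.cluster_centers_, float(km.inertia_)


def fit_cluster_model(table: pd.DataFrame, k: int,
                      features: list[str] | None = None,
                      n_init: int = 25, seed: int = 0) -> ClusterModel:
    features = list(features or COMPOSITION_FEATURES)
    Z, params = zscore(table, features)
    labels, centroids, inertia = kmeans_cluster(Z, k, n_init=n_init, seed=seed)
    return ClusterModel(
        feature_names=features, standardization=params, k=k,
        centroids=centroids, labels=labels, inertia=inertia,
        n_init=n_init, seed=seed,
    )


def dunn_index(Z: np.ndarray, labels: np.ndarray) -> float:
    """min inter-cluster single-linkage distance / max intra diameter."""
    Z = np.asarray(Z, dtype=float)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        return np.nan
    groups = [Z[labels == u] for u in uniq]
    max_diam = 0.0
    for g in groups:
        if len(g) > 1:
            max_diam = max(max_diam, float(pdist(g).max()))
    min_sep = np.inf
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            min_sep = min(min_sep, float(cdist(groups[i], groups[j]).min()))
    if max_diam == 0:
        return np.inf
    return min_sep / max_diam


@dataclass
class KSelectionReport:
    table: pd.DataFrame          # k, silhouette, dunn, ch, mean_ari, flagged
    chosen_k: int
    rationale: str


def k_selection(Z: np.ndarray, k_candidates: list[int], n_repeats: int = 10,
                n_init: int = 25, seed: int = 0) -> KSelectionReport:
    """Screen candidate k by validity indices and repeat-run consistency.

    Candidates are ranked on each index (higher better for all four);
    the chosen k has the best mean rank, ties broken toward smaller k.
    A candidate that yields an empty cluster is flagged and never chosen.
    """
    Z = np.asarray(Z, dtype=float)
    n = len(Z)
    rows = []
    for k in sorted(k_candidates):
        if not 2 <= k <= n // 10:
            raise ValueError(f"candidate k={k} outside 2..{n // 10}")
        try:
            labels, _, _ = kmeans_cluster(Z, k, n_init=n_init, seed=seed)
        except RuntimeError:
            rows.append({"k": k, "silhouette": np.nan, "dunn": np.nan,
                         "ch": np.nan, "mean_ari": np.nan, "flagged": True})
            continue
        repeat_labels = [
            kmeans_cluster(Z, k, n_init=1, seed=seed + 1000 * (r + 1))[0]
            for r in range(n_repeats)
        ]
        aris = [
            adjusted_rand_score(repeat_labels[i], repeat_labels[j])
            for i in range(n_repeats) for j in range(i + 1, n_repeats)
        ]
        rows.append({
            "k": k,
            "silhouette": silhouette_score(Z, labels),
            "dunn": dunn_index(Z, labels),
            "ch": calinski_harabasz_score(Z, labels),
            "mean_ari": float(np.mean(aris)) if aris else np.nan,
            "flagged": False,
        })
    table = pd.DataFrame(rows)
    ok = table[~table["flagged"]]
    if ok.empty:
        raise RuntimeError("no candidate k produced a usable partition")
    ranks = ok[["silhouette", "dunn", "ch", "mean_ari"]].rank(ascending=False)
    mean_rank = ranks.mean(axis=1)
    # stable sort on k (ascending) breaks mean-rank ties toward smaller k
    best = ok.loc[mean_rank.sort_values(kind="stable").index[0], "k"]
    rationale = (
        f"best mean rank across silhouette/Dunn/CH/ARI "
        f"(ties toward smaller k); chosen k={int(best)}"
    )
    return KSelectionReport(table=table, chosen_k=int(best),
                            rationale=rationale)


# ---------------------------------------------------------------------------
# Moran's I diagnostics on the unit lattice


def rook_weights(n_rows: int, n_cols: int) -> np.ndarray:
    """Row-standardized rook-adjacency weight matrix for a full lattice."""
    n = n_rows * n_cols
    W = np.zeros((n, n))
    for r in range(n_rows):
        for c in range(n_cols):
            i = r * n_cols + c
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols:
                    W[i, rr * n_cols + cc] = 1.0
    W /= W.sum(axis=1, keepdims=True)
    return W


def morans_i(z: np.ndarray, W: np.ndarray) -> float:
    """Moran's I of a variable under row-standardized weights."""
    z = np.asarray(z, dtype=float)
    zc = z - z.mean()
    denom = float(zc @ zc)
    if denom == 0:
        return np.nan
    # row-standardized: sum of weights equals n, so n/S0 = 1
    return float(zc @ (W @ zc)) / denom


def permutation_morans_i(z: np.ndarray, W: np.ndarray, n_permutations: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Moran's I for random permutations of z, batched."""
    zc = np.asarray(z, dtype=float) - np.mean(z)
    denom = float(zc @ zc)
    perms = rng.permuted(
        np.tile(zc, (n_permutations, 1)), axis=1
    )
    return ((perms @ W.T) * perms).sum(axis=1) / denom


def cluster_morans_i(labels: np.ndarray, n_rows: int, n_cols: int,
                     n_permutations: int = 999, seed: int = 0
                     ) -> pd.DataFrame:
    """Per-cluster Moran's I of the one-vs-rest indicator, permutation p.

    Clusters with fewer than 2 members are flagged undefined.  The
    permutation p-value is (1 + #{|I_perm| >= |I_obs|}) / (B + 1),
    two-sided, seeded.
    """
    labels = np.asarray(labels)
    if labels.size != n_rows * n_cols:
        raise ValueError("labels do not match the unit lattice size")
    W = rook_weights(n_rows, n_cols)
    rng = np.random.default_rng(seed)
    rows = []
    for cl in np.unique(labels):
        ind = (labels == cl).astype(float)
        if ind.sum() < 2:
            rows.append({"cluster": cl, "morans_i": np.nan, "p": np.nan,
                         "defined": False})
            continue
        i_obs = morans_i(ind, W)
        perm = permutation_morans_i(ind, W, n_permutations, rng)
        p = (1 + int((np.abs(perm) >= abs(i_obs)).sum())) / (n_permutations + 1)
        rows.append({"cluster": cl, "morans_i": i_obs, "p": p,
                     "defined": True})
    return pd.DataFrame(rows)
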