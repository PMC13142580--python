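"""Network-feature subtyping of patients by k-means with split-half validation.

Patients are clustered on their FDR-significant region x metric network
features (column-standardized), reduced to the first principal components
for separability. The two-cluster solution is validated by 1:1 split-half
cross-validation with optimal centroid matching; the S1/S2 label identity
is anchored by the anterior-cingulate contrast (S1 = lower ACC values).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

log = logging.getLogger(__name__)


def build_feature_matrix(
    patient_features: dict, significant: dict
) -> tuple[np.ndarray, list]:
    """Column-standardized patients x significant-features matrix.

    Parameters
    ----------
    patient_features : dict of metric -> (patients x 68) arrays
    significant : dict of metric -> boolean mask (length 68) of
        FDR-significant regions for that metric.

    Returns the standardized matrix and the feature names
    ``<metric>:<region index>``.
    """
    blocks, names = [], []
    for metric, mask in significant.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.any():
            blocks.append(np.asarray(patient_features[metric], dtype=float)[:, mask])
            names += [f"{metric}:{i}" for i in np.flatnonzero(mask)]
    if not blocks:
        raise ValueError("zero significant features; nothing to cluster")
    M = np.hstack(blocks)
    M = (M - M.mean(axis=0)) / M.std(axis=0, ddof=1)
    return M, names


@dataclass
class SubtypeResult:
    labels: np.ndarray  # 1 or 2 per patient
    centroids: np.ndarray
    sse_curve: dict  # k -> SSE
    pc_variance: np.ndarray | None = None
    concordance: tuple | None = None
    k: int = 2


def pca_reduce(features: np.ndarray, n_pc: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """PCA scores and per-component variance fractions."""
    pca = PCA(n_components=n_pc, svd_solver="full")
    scores = pca.fit_transform(np.asarray(features, dtype=float))
    return scores, pca.explained_variance_ratio_


def kmeans_scan(
    features: np.ndarray,
    k_range: range = range(2, 10),
    n_init: int = 50,
    seed: int = 0,
    chosen_k: int = 2,
) -> SubtypeResult:
    """SSE over k = 2..9 plus labels at the chosen k (best of n_init restarts)."""
    X = np.asarray(features, dtype=float)
    sse = {}
    chosen = None
    for k in k_range:
        if k > len(X):
            raise ValueError(f"k={k} exceeds n={len(X)}")
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        km.fit(X)
        sse[k] = float(km.inertia_)
        if k == chosen_k:
            chosen = km
    if chosen is None:
        chosen = KMeans(n_clusters=chosen_k, n_init=n_init, random_state=seed).fit(X)
    return SubtypeResult(
        labels=chosen.labels_ + 1,
        centroids=chosen.cluster_centers_,
        sse_curve=sse,
        k=chosen_k,
    )


def _match_labels(centroids_a: np.ndarray, centroids_b: np.ndarray) -> np.ndarray:
    """Map B's cluster ids onto A's by minimal centroid-distance assignment."""
    cost = cdist(centroids_a, centroids_b)
    rows, cols = linear_sum_assignment(cost)
    mapping = np.empty(len(centroids_b), dtype=int)
    mapping[cols] = rows
    return mapping


def split_half_concordance(
    features: np.ndarray,
    k: int = 2,
    seed: int = 0,
    n_init: int = 50,
    max_retry: int = 5,
) -> tuple[float, float]:
    """Assignment concordance between independent half-sample clusterings.

    The sample is split 1:1 at random. k-means is fitted on half A; half B
    is assigned to the nearest A-centroid; an independent k-means on half
    B is label-matched to A by optimal centroid assignment; the
    concordance is the fraction of half-B patients labeled identically by
    both routes. The procedure is repeated with the halves swapped.
    """
    X = np.asarray(features, dtype=float)
    if len(X) < 20:
        raise ValueError("need at least 20 patients for split-half validation")
    rng = np.random.default_rng(seed)
    for attempt in range(max_retry):
        perm = rng.permutation(len(X))
        half = len(X) // 2
        A, B = perm[:half], perm[half:]
        try:
            out = []
            for train, test in ((A, B), (B, A)):
                km_train = KMeans(n_clusters=k, n_init=n_init,
                                  random_state=seed).fit(X[train])
                km_test = KMeans(n_clusters=k, n_init=n_init,
                                 random_state=seed + 1).fit(X[test])
                assigned = np.argmin(cdist(X[test], km_train.cluster_centers_), axis=1)
                if len(np.unique(assigned)) < k:
                    raise RuntimeError("empty cluster after nearest-centroid assignment")
                mapping = _match_labels(km_train.cluster_centers_, km_test.cluster_centers_)
                native = mapping[km_test.labels_]
                out.append(float(np.mean(native == assigned)))
            return tuple(out)
        except RuntimeError:
            log.info("split_half_concordance: empty cluster, re-splitting (attempt %d)", attempt + 1)
    raise RuntimeError(f"split-half validation failed after {max_retry} re-splits")


def anchor_subtype_labels(
    labels: np.ndarray, acc_values: np.ndarray
) -> np.ndarray:
    """Fix S1/S2 identity: S1 is the cluster with the lower mean ACC value."""
    labels = np.asarray(labels)
    m1 = acc_values[labels == 1].mean()
    m2 = acc_values[labels == 2].mean()
    if m1 <= m2:
        return labels
    return np.where(labels == 1, 2, 1)
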