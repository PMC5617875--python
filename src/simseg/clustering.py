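"""Coarse-graining of DFT feature rows into K clusters plus a nuisance bin.

k-means runs on the expressed (non-nuisance) positions only; cluster labels
are 1..K, with 0 reserved for the nuisance cluster of non-expressed or
poorly fitting positions.  Two Pearson-correlation matrices drive the
downstream segmentation scores:

* ``pos_cluster_sim``  (n x K): correlation of each position's feature row
  with each cluster mean — the basis of the ``icor`` scoring function;
* ``cluster_cluster_sim`` (K x K): correlation between cluster means — the
  basis of ``ccor``.

Positions whose correlation to their own center falls below a threshold
theta (``nui.thresh``, default 0.6) are re-assigned to the nuisance cluster.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.cluster import KMeans

from .timeseries import ProcessedSeries

logger = logging.getLogger(__name__)

_KMEANS_RETRIES = 3


@dataclass
class ClusterModel:
    """Cluster labels, centers, and the similarity matrices built from them."""

    labels: np.ndarray  # (n,) int in {0..K}, 0 = nuisance
    centers: np.ndarray  # (K, m) feature-space means
    K: int
    theta: float = 0.6
    seed: int = 0
    pos_cluster_sim: Optional[np.ndarray] = None  # (n, K)
    cluster_cluster_sim: Optional[np.ndarray] = None  # (K, K)

    @property
    def n(self) -> int:
        return self.labels.shape[0]


def _pearson_rows(rows: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row with each center, across features.

    Zero-variance rows or centers get correlation 0 by convention so that
    downstream scoring matrices stay finite.
    """
    m = rows.shape[1]
    if m < 2:
        raise ValueError("Pearson correlation needs >= 2 feature columns")
    rz = rows - rows.mean(axis=1, keepdims=True)
    cz = centers - centers.mean(axis=1, keepdims=True)
    rs = np.sqrt((rz**2).sum(axis=1))
    cs = np.sqrt((cz**2).sum(axis=1))
    num = rz @ cz.T
    denom = rs[:, None] * cs[None, :]
    out = np.zeros_like(num)
    np.divide(num, denom, out=out, where=denom > 0)
    return np.clip(out, -1.0, 1.0)


def kmeans_cluster(series: ProcessedSeries, K: int, seed: int = 0, n_init: int = 10) -> ClusterModel:
    """Cluster expressed positions into K groups; nuisance keeps label 0.

    Deterministic given ``seed``.  An empty cluster after convergence is
    retried with a re-derived seed up to a bounded number of times.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    expressed = ~series.nuisance_flag
    n_expr = int(expressed.sum())
    if n_expr < K:
        raise ValueError(f"only {n_expr} expressed positions for K={K}")
    X = series.features[expressed]
    labels_expr = None
    centers = None
    for attempt in range(_KMEANS_RETRIES):
        km = KMeans(n_clusters=K, random_state=(seed + attempt) % 2**31, n_init=n_init)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # duplicate-point convergence noise
            fit = km.fit(X)
        if len(np.unique(fit.labels_)) == K:
            labels_expr = fit.labels_
            centers = fit.cluster_centers_
            break
    if labels_expr is None:
        raise ValueError(f"k-means produced an empty cluster in {_KMEANS_RETRIES} attempts")
    labels = np.zeros(series.n, dtype=int)
    labels[expressed] = labels_expr + 1  # 1-based real clusters
    # centers as plain cluster means in feature space (recomputed; sklearn's
    # centers equal these after convergence but we do not rely on it)
    means = np.vstack([X[labels_expr == a].mean(axis=0) for a in range(K)])
    return ClusterModel(labels=labels, centers=means, K=K, seed=seed)


def build_similarities(series: ProcessedSeries, model: ClusterModel) -> ClusterModel:
    """Fill the position-cluster and cluster-cluster Pearson matrices."""
    if model.centers is None:
        raise ValueError("model.centers must be defined")
    cz = model.centers - model.centers.mean(axis=1, keepdims=True)
    if np.any((cz**2).sum(axis=1) == 0):
        logger.warning("cluster center with zero variance; its column is set to 0")
    model.pos_cluster_sim = _pearson_rows(series.features, model.centers)
    ccs = _pearson_rows(model.centers, model.centers)
    np.fill_diagonal(ccs, 1.0)
    model.cluster_cluster_sim = ccs
    return model


def reassign_nuisance(model: ClusterModel, theta: Optional[float] = None) -> ClusterModel:
    """Send positions correlating below theta with their own center to label 0."""
    theta = model.theta if theta is None else theta
    if not (-1.0 <= theta <= 1.0):
        raise ValueError(f"theta must be in [-1, 1], got {theta}")
    if model.pos_cluster_sim is None:
        raise ValueError("similarity matrices must be filled first")
    model.theta = theta
    labeled = model.labels >= 1
    own = model.pos_cluster_sim[np.arange(model.n), np.maximum(model.labels - 1, 0)]
    drop = labeled & (own < theta)
    model.labels = model.labels.copy()
    model.labels[drop] = 0
    return model


def sort_clusters_by_similarity(model: ClusterModel) -> ClusterModel:
    """Relabel clusters along a greedy nearest-neighbor chain (cosmetic).

    Starts at the cluster with the strongest off-diagonal similarity and
    repeatedly appends the unvisited cluster most similar to the last one.
    All matrices and labels are permuted consistently, so downstream scores
    are unchanged.
    """
    if model.cluster_cluster_sim is None:
        raise ValueError("cluster_cluster_sim must be filled first")
    K = model.K
    sim = model.cluster_cluster_sim
    if K == 1:
        return model
    off = np.where(np.eye(K, dtype=bool), -np.inf, sim)
    start = int(np.argmax(off.max(axis=1)))
    order = [start]
    remaining = set(range(K)) - {start}
    while remaining:
        last = order[-1]
        nxt = max(sorted(remaining), key=lambda b: (sim[last, b], -b))
        order.append(nxt)
        remaining.discard(nxt)
    perm = np.asarray(order)  # new index a <- old index perm[a]
    inv = np.empty(K, dtype=int)
    inv[perm] = np.arange(K)
    new_labels = model.labels.copy()
    mask = model.labels >= 1
    new_labels[mask] = inv[model.labels[mask] - 1] + 1
    model.labels = new_labels
    model.centers = model.centers[perm]
    if model.pos_cluster_sim is not None:
        model.pos_cluster_sim = model.pos_cluster_sim[:, perm]
    model.cluster_cluster_sim = sim[np.ix_(perm, perm)]
    return model
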