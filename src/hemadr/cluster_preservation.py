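"""Cluster preservation under dimension reduction.

Clusters found in the scaled original data serve as ground truth; each
reduced embedding is clustered with the same model and the agreement is
scored with NMI and ARI, both implemented from their contingency-table
definitions. Density clustering (HDBSCAN) runs through an adapter; k-means
is a native Lloyd implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import comb

from .reducers import DependencyError, ReducerConfig, reduce_matrix

__all__ = [
    "Partition",
    "ClusterComparisonReport",
    "kmeans_cluster",
    "density_cluster",
    "contingency",
    "nmi",
    "ari",
    "cluster_preservation_report",
]

NOISE = -1


@dataclass
class Partition:
    """Per-sample integer cluster labels; -1 marks density-clustering noise."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_clusters(self) -> int:
        """Number of non-noise clusters."""
        return len(set(self.labels.tolist()) - {NOISE})


@dataclass
class ClusterComparisonReport:
    method: str
    n_components: int | None
    n_clusters_original: int
    n_clusters_reduced: int
    nmi: float
    ari: float


def _kmeans_pp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: each next centre drawn with probability
    proportional to squared distance from the nearest chosen centre."""
    n = X.shape[0]
    centres = np.empty((k, X.shape[1]))
    centres[0] = X[rng.integers(n)]
    d2 = ((X - centres[0]) ** 2).sum(axis=1)
    for c in range(1, k):
        total = d2.sum()
        if total == 0:
            centres[c:] = X[rng.integers(n, size=k - c)]
            break
        probs = d2 / total
        centres[c] = X[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, ((X - centres[c]) ** 2).sum(axis=1))
    return centres


def kmeans_cluster(X: np.ndarray, k: int, seed: int = 0,
                   max_iter: int = 300) -> Partition:
    """Lloyd's k-means from seeded k-means++ centres.

    Iterates assignment/update until the assignment reaches a fixpoint or
    ``max_iter``; an emptied cluster is re-seeded at the point farthest from
    its nearest centre. Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples {n}")
    rng = np.random.default_rng(seed)
    centres = _kmeans_pp_init(X, k, rng)
    labels = np.full(n, -1)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centres[None, :, :]) ** 2).sum(axis=2) \
            if n * k * X.shape[1] < 5e7 else None
        if d2 is None:  # chunked for large problems
            d2 = np.empty((n, k))
            for c in range(k):
                d2[:, c] = ((X - centres[c]) ** 2).sum(axis=1)
        new_labels = d2.argmin(axis=1)
        for c in range(k):
            if not np.any(new_labels == c):  # empty cluster: farthest point
                far = d2[np.arange(n), new_labels].argmax()
                new_labels[far] = c
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            centres[c] = X[labels == c].mean(axis=0)
    return Partition(labels)


def density_cluster(X: np.ndarray, min_cluster_size: int = 50) -> Partition:
    """HDBSCAN adapter; noise points get label -1."""
    try:
        from sklearn.cluster import HDBSCAN
    except ImportError as exc:
        raise DependencyError("HDBSCAN backend is not installed") from exc
    X = np.asarray(X, dtype=float)
    if np.ptp(X, axis=0).max(initial=0.0) == 0.0:
        # degenerate input: every point identical is one maximally dense
        # cluster, not noise (the backend labels it all-noise)
        return Partition(np.zeros(len(X), dtype=int))
    labels = HDBSCAN(min_cluster_size=min_cluster_size, copy=True).fit_predict(X)
    return Partition(labels)


def contingency(a: Partition, b: Partition,
                drop_noise: bool = False) -> np.ndarray:
    """Cross-tabulation of two labelings.

    Noise (-1) forms its own pseudo-cluster unless ``drop_noise``, in which
    case samples noisy in either partition are excluded.
    """
    la, lb = a.labels, b.labels
    if len(la) != len(lb):
        raise ValueError("partitions must cover the same samples")
    if drop_noise:
        keep = (la != NOISE) & (lb != NOISE)
        la, lb = la[keep], lb[keep]
    ua, ia = np.unique(la, return_inverse=True)
    ub, ib = np.unique(lb, return_inverse=True)
    m = np.zeros((len(ua), len(ub)), dtype=np.int64)
    np.add.at(m, (ia, ib), 1)
    return m


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def nmi(a: Partition, b: Partition, drop_noise: bool = False) -> float:
    """Normalised mutual information, arithmetic-mean normaliser.

    1.0 when both partitions are single-cluster (degenerate but identical);
    0.0 when either entropy is zero and the partitions differ.
    """
    m = contingency(a, b, drop_noise=drop_noise)
    total = m.sum()
    if total == 0:
        raise ValueError("no samples to compare")
    ha, hb = _entropy(m.sum(axis=1)), _entropy(m.sum(axis=0))
    if ha == 0.0 and hb == 0.0:
        return 1.0
    if ha == 0.0 or hb == 0.0:
        return 0.0
    pij = m / total
    pa = m.sum(axis=1) / total
    pb = m.sum(axis=0) / total
    nz = pij > 0
    mi = float((pij[nz] * np.log(pij[nz] / np.outer(pa, pb)[nz])).sum())
    return mi / ((ha + hb) / 2.0)


def ari(a: Partition, b: Partition, drop_noise: bool = False) -> float:
    """Adjusted Rand index via pair counting on the contingency table."""
    m = contingency(a, b, drop_noise=drop_noise)
    n = m.sum()
    if n < 2:
        raise ValueError("need at least 2 samples")
    sum_ij = comb(m, 2).sum()
    sum_a = comb(m.sum(axis=1), 2).sum()
    sum_b = comb(m.sum(axis=0), 2).sum()
    n_pairs = comb(n, 2)
    expected = sum_a * sum_b / n_pairs
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:  # both partitions trivial (one cluster / all singletons)
        one_to_one = (np.count_nonzero(m, axis=0) <= 1).all() and \
            (np.count_nonzero(m, axis=1) <= 1).all()
        return 1.0 if one_to_one else 0.0
    return float((sum_ij - expected) / (max_index - expected))


def cluster_preservation_report(X_scaled: np.ndarray,
                                reducer_configs: list[ReducerConfig],
                                clusterer: str = "hdbscan",
                                min_cluster_size: int = 50,
                                seed: int = 0,
                                on_error: str = "skip"
                                ) -> list[ClusterComparisonReport]:
    """Cluster the scaled original data once as ground truth, then each
    reduced embedding, and report counts, NMI and ARI per configuration.

    ``clusterer`` is "hdbscan" or "kmeans"; for k-means, k defaults to the
    ground-truth cluster count found by HDBSCAN on the original data.
    Backend failures are skipped (recorded as a report with NaN scores) when
    ``on_error="skip"`` so the run continues with the remaining methods.
    """
    X_scaled = np.asarray(X_scaled, dtype=float)

    def _cluster(X: np.ndarray, k_hint: int | None) -> Partition:
        if clusterer == "hdbscan":
            return density_cluster(X, min_cluster_size=min_cluster_size)
        if clusterer == "kmeans":
            k = k_hint if k_hint else 8
            return kmeans_cluster(X, k, seed=seed)
        raise ValueError(f"unknown clusterer {clusterer!r}")

    k_hint = None
    if clusterer == "kmeans":
        k_hint = density_cluster(X_scaled, min_cluster_size=min_cluster_size).n_clusters or 8
    truth = _cluster(X_scaled, k_hint)
    reports = [ClusterComparisonReport("original", None, truth.n_clusters,
                                       truth.n_clusters, 1.0, 1.0)]
    for cfg in reducer_configs:
        try:
            emb = reduce_matrix(X_scaled, cfg)
            part = _cluster(emb.coordinates, truth.n_clusters or k_hint)
            reports.append(ClusterComparisonReport(
                cfg.method, cfg.n_components, truth.n_clusters,
                part.n_clusters, nmi(truth, part), ari(truth, part)))
        except DependencyError:
            if on_error != "skip":
                raise
            reports.append(ClusterComparisonReport(
                cfg.method, cfg.n_components, truth.n_clusters, 0,
                float("nan"), float("nan")))
    return reports
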