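"""Clustering and imputation benchmark metrics.

All metrics are implemented directly from their defining formulas (rather
than delegated to a library) so each can be validated against an
independent brute-force oracle:

* clustering — adjusted Rand index (ARI), normalized mutual information
  (NMI, geometric-mean-of-entropies denominator), homogeneity score (HS),
  and the Davies–Bouldin index (DBI) used internally for run selection;
* imputation — Pearson correlation, mean squared error, Spearman rank
  correlation (mid-rank ties), and cosine similarity.

Entropies use natural logarithms; the base cancels in every ratio.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import xlogy
from scipy.stats import rankdata

__all__ = [
    "contingency_table",
    "adjusted_rand_index",
    "normalized_mutual_information",
    "homogeneity_score",
    "davies_bouldin",
    "pearson",
    "mean_squared_error_metric",
    "spearman",
    "cosine_similarity_metric",
]


def contingency_table(true, pred) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Joint counts ``n_ij`` plus marginals ``a_i`` (true) and ``b_j`` (pred)."""
    true = np.asarray(true)
    pred = np.asarray(pred)
    if true.shape != pred.shape or true.ndim != 1:
        raise ValueError("label vectors must be 1-D and the same length")
    _, ti = np.unique(true, return_inverse=True)
    _, pi = np.unique(pred, return_inverse=True)
    r, c = ti.max() + 1, pi.max() + 1
    nij = np.zeros((r, c), dtype=np.int64)
    np.add.at(nij, (ti, pi), 1)
    return nij, nij.sum(axis=1), nij.sum(axis=0), int(true.size)


def _comb2(x: np.ndarray) -> np.ndarray:
    return x * (x - 1) / 2.0


def adjusted_rand_index(true, pred) -> float:
    """Chance-corrected pair-counting agreement between two labelings."""
    nij, a, b, n = contingency_table(true, pred)
    if n < 2:
        raise ValueError("need at least 2 samples")
    sum_ij = _comb2(nij.astype(float)).sum()
    sum_a = _comb2(a.astype(float)).sum()
    sum_b = _comb2(b.astype(float)).sum()
    expected = sum_a * sum_b / _comb2(float(n))
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        # both partitions trivial (all-singletons or single cluster): perfect
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def _entropy(counts: np.ndarray, n: int) -> float:
    p = counts[counts > 0] / n
    return float(-np.sum(p * np.log(p)))


def normalized_mutual_information(true, pred) -> float:
    """Mutual information normalized by the geometric mean of the entropies."""
    nij, a, b, n = contingency_table(true, pred)
    ha, hb = _entropy(a, n), _entropy(b, n)
    if ha == 0 or hb == 0:
        warnings.warn("single-cluster labeling: NMI undefined, returning 0")
        return 0.0
    outer = np.outer(a, b).astype(float)
    mi = float(np.sum(xlogy(nij, n * nij / np.where(outer > 0, outer, 1.0))) / n)
    return mi / np.sqrt(ha * hb)


def homogeneity_score(true, pred) -> float:
    """``1 - H(C|K)/H(C)``: 1 iff every predicted cluster is class-pure."""
    nij, a, b, n = contingency_table(true, pred)
    hc = _entropy(a, n)
    if hc == 0:
        return 1.0
    # H(C|K) = -sum_ij (n_ij/n) log(n_ij / b_j)
    bj = np.broadcast_to(b[None, :], nij.shape).astype(float)
    hck = float(-np.sum(xlogy(nij / n, nij / np.where(bj > 0, bj, 1.0))))
    return 1.0 - hck / hc


def davies_bouldin(points: np.ndarray, labels) -> float:
    """Mean over clusters of the worst (scatter_i + scatter_j) / separation_ij.

    Scatter is the mean Euclidean distance to the cluster centroid;
    separation the centroid-centroid distance.  Lower is better.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k = len(uniq)
    if k < 2:
        raise ValueError("Davies-Bouldin requires at least 2 clusters")
    centroids = np.stack([points[labels == u].mean(axis=0) for u in uniq])
    scatter = np.array(
        [
            np.mean(np.linalg.norm(points[labels == u] - centroids[i], axis=1))
            for i, u in enumerate(uniq)
        ]
    )
    sep = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=2)
    ratios = np.full((k, k), -np.inf)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            if sep[i, j] == 0:
                raise ValueError(
                    f"coincident centroids for clusters {uniq[i]} and {uniq[j]}"
                )
            ratios[i, j] = (scatter[i] + scatter[j]) / sep[i, j]
    return float(np.mean(ratios.max(axis=1)))


def pearson(x, y) -> float:
    """Pearson linear correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must be the same length")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    if denom == 0:
        raise ValueError("constant vector: Pearson correlation undefined")
    return float(np.sum(xc * yc) / denom)


def mean_squared_error_metric(x, y) -> float:
    """Mean of squared elementwise differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must be the same length")
    return float(np.mean((x - y) ** 2))


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson on mid-rank-tied ranks."""
    return pearson(rankdata(x), rankdata(y))


def cosine_similarity_metric(x, y) -> float:
    """Cosine of the angle between two non-zero vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(x, y) / (nx * ny))
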