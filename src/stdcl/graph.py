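"""Transcriptomics-profile-based spatial graph construction.

Two binary k-nearest-neighbor graphs are built — one over spatial
coordinates (k1 neighbors) and one over expression profiles (k2 neighbors)
— OR-symmetrized, and fused as

    A = min(A_spatial + alpha * A_gene, 1),     alpha in (0, 1]

so spatial adjacency takes precedence and expression adjacency supplements
it with weight ``alpha``.  Clipping at 1 prevents doubly-connected pairs
from being over-weighted.  The GCN propagation matrix adds self-loops:
``A_norm = D^{-1/2} (A + I) D^{-1/2}`` with ``D = diag((A + I) 1)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "NeighborGraph",
    "knn_adjacency",
    "combine_graphs",
    "normalize_adjacency",
    "build_graph",
    "write_edge_list",
    "read_edge_list",
]

_METRICS = {"euclidean": "euclidean", "cosine": "cosine", "manhattan": "cityblock"}


@dataclass
class NeighborGraph:
    """The fused weighted adjacency and its construction parameters."""

    A: np.ndarray
    A_spatial: np.ndarray
    A_gene: np.ndarray
    k1: int
    k2: int
    alpha: float
    A_norm: np.ndarray

    @property
    def n_spots(self) -> int:
        return self.A.shape[0]


def knn_adjacency(
    points: np.ndarray,
    k: int,
    metric: Literal["euclidean", "cosine", "manhattan"] = "euclidean",
) -> np.ndarray:
    """Binary symmetrized k-nearest-neighbor adjacency.

    The directed top-k relation (self excluded) is symmetrized by logical
    OR, so every row has at least ``k`` nonzeros.  Distance ties are broken
    by ascending point index (stable sort), making the graph deterministic
    for duplicated points.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if not 0 < k < n:
        raise ValueError(f"k must satisfy 0 < k < n_points; got k={k}, n={n}")
    if metric not in _METRICS:
        raise ValueError(f"unknown metric: {metric!r}")
    D = cdist(points, points, metric=_METRICS[metric])
    np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1, kind="stable")
    A = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    A[rows, order[:, :k].ravel()] = 1.0
    A = np.maximum(A, A.T)
    return A


def combine_graphs(
    A_spatial: np.ndarray, A_gene: np.ndarray, alpha: float
) -> np.ndarray:
    """Fuse the two binary graphs: ``min(A_spatial + alpha * A_gene, 1)``."""
    if A_spatial.shape != A_gene.shape:
        raise ValueError(
            f"shape mismatch: {A_spatial.shape} vs {A_gene.shape}"
        )
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    return np.minimum(A_spatial + alpha * A_gene, 1.0)


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric GCN normalization with self-loops.

    Returns ``D^{-1/2} (A + I) D^{-1/2}`` where ``D = diag((A + I) 1)``.
    Every degree is at least 1 (the self-loop), so isolated spots are safe:
    their normalized row is the unit basis row.
    """
    A = np.asarray(A, dtype=float)
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    A_tilde = A + np.eye(A.shape[0])
    d = A_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return A_tilde * inv_sqrt[:, None] * inv_sqrt[None, :]


def build_graph(
    coords: np.ndarray,
    X: np.ndarray,
    k1: int = 3,
    k2: int = 3,
    alpha: float = 0.5,
    metric: Literal["euclidean", "cosine", "manhattan"] = "euclidean",
    expr_pcs: int | None = 50,
    mode: Literal["fused", "spatial_only", "gene_only"] = "fused",
) -> NeighborGraph:
    """Construct the fused neighbor graph and its GCN-normalized form.

    The expression kNN graph is computed on a PCA reduction of ``X`` (top
    ``expr_pcs`` components, default 50) for robustness; pass
    ``expr_pcs=None`` to use the raw processed matrix.  ``mode`` supports
    the ablations: ``spatial_only`` drops the expression edges and
    ``gene_only`` drops the spatial edges.
    """
    A_spatial = knn_adjacency(coords, k1, metric=metric)
    feats = np.asarray(X, dtype=float)
    if expr_pcs is not None and 0 < expr_pcs < min(feats.shape):
        from sklearn.decomposition import PCA

        feats = PCA(n_components=expr_pcs, svd_solver="full").fit_transform(feats)
    A_gene = knn_adjacency(feats, k2, metric=metric)
    if mode == "fused":
        A = combine_graphs(A_spatial, A_gene, alpha)
    elif mode == "spatial_only":
        A = A_spatial.copy()
    elif mode == "gene_only":
        A = A_gene.copy()
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    return NeighborGraph(
        A=A,
        A_spatial=A_spatial,
        A_gene=A_gene,
        k1=k1,
        k2=k2,
        alpha=alpha,
        A_norm=normalize_adjacency(A),
    )


def write_edge_list(A: np.ndarray, path: str | os.PathLike) -> Path:
    """Export a weighted adjacency as a 3-column (i, j, weight) TSV."""
    path = Path(path)
    i, j = np.nonzero(np.triu(A, k=1))
    pd.DataFrame({"i": i, "j": j, "weight": A[i, j]}).to_csv(
        path, sep="\t", index=False
    )
    return path


def read_edge_list(path: str | os.PathLike, n_spots: int) -> np.ndarray:
    """Read a 3-column edge-list TSV back into a symmetric dense matrix."""
    df = pd.read_csv(path, sep="\t")
    A = np.zeros((n_spots, n_spots))
    A[df["i"], df["j"]] = df["weight"]
    A[df["j"], df["i"]] = df["weight"]
    return A
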