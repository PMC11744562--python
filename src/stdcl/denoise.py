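"""Latent-space denoising, interpretable-gene ranking and imputation checks.

Denoising averages each spot's expression with its nearest neighbors in
the *latent* embedding (default 15 neighbors, Euclidean distance), so
smoothing respects learned domain structure rather than raw spatial
proximity.  Gene interpretability ranks genes by the standard deviation of
their encoder-weight rows: a gene whose weights vary strongly across
latent dimensions contributes discriminative structure to the embedding.
The imputation-space check projects the reconstructed expression to 2-D
and compares all-pairs distances against the original expression space
with four correlation/consistency metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.spatial.distance import pdist

from .metrics import (
    cosine_similarity_metric,
    mean_squared_error_metric,
    pearson,
    spearman,
)
from .model import ModelState

__all__ = [
    "DenoisedExpression",
    "denoise_expression",
    "interpretable_gene_ranking",
    "imputation_space_correlation",
]


@dataclass
class DenoisedExpression:
    """Neighbor-averaged expression matrix with the parameters used."""

    X_denoised: np.ndarray
    k_neighbors: int
    include_self: bool


def denoise_expression(
    X: np.ndarray,
    Z: np.ndarray,
    k: int = 15,
    include_self: bool = True,
) -> DenoisedExpression:
    """Average expression over each spot's k nearest latent-space neighbors.

    The spot's own row is included in the average by default.
    """
    n = X.shape[0]
    if not 0 < k < n:
        raise ValueError(f"k must satisfy 0 < k < n_spots; got k={k}, n={n}")
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=k + 1).fit(Z)
    _, idx = nn.kneighbors(Z)  # column 0 is the spot itself
    if include_self:
        Xd = X[idx].mean(axis=1)
    else:
        Xd = X[idx[:, 1:]].mean(axis=1)
    return DenoisedExpression(X_denoised=Xd, k_neighbors=k, include_self=include_self)


def interpretable_gene_ranking(model: ModelState, top_m: int = 1000) -> np.ndarray:
    """Rank genes by descending standard deviation of their encoder-weight row.

    Returns the indices of the ``top_m`` highest-ranked genes.  The ranking
    is invariant to any permutation of the latent dimensions; ties are
    broken by ascending gene index.
    """
    if top_m <= 0:
        raise ValueError(f"top_m must be positive, got {top_m}")
    n_genes = model.W_e.shape[0]
    if top_m > n_genes:
        raise ValueError(f"top_m={top_m} exceeds {n_genes} genes")
    stds = model.W_e.std(axis=1)
    order = np.argsort(-stds, kind="stable")
    return order[:top_m]


def imputation_space_correlation(
    X_original: np.ndarray,
    H: np.ndarray,
    projector: Literal["umap", "pca", "identity"] = "umap",
    seed: int = 0,
) -> dict[str, float]:
    """Compare pairwise distances in the imputation space with the original.

    ``H`` is projected to 2-D (UMAP by default; PCA for a fully
    deterministic alternative; ``identity`` skips projection), then the
    flattened upper-triangular Euclidean distance vectors of the original
    space and the projection are compared with Pearson correlation, MSE,
    Spearman rank correlation and cosine similarity.
    """
    if X_original.shape[0] != H.shape[0]:
        raise ValueError("matrices must be aligned on spots")
    if X_original.shape[0] < 3:
        raise ValueError("need at least 3 spots")
    if projector == "identity":
        E = H
    elif projector == "pca":
        from sklearn.decomposition import PCA

        E = PCA(n_components=2, svd_solver="full").fit_transform(H)
    elif projector == "umap":
        import umap

        E = umap.UMAP(n_components=2, random_state=seed).fit_transform(H)
    else:
        raise ValueError(f"unknown projector: {projector!r}")
    d_orig = pdist(X_original)
    d_imp = pdist(E)
    return {
        "pcc": pearson(d_orig, d_imp),
        "mse": mean_squared_error_metric(d_orig, d_imp),
        "srcc": spearman(d_orig, d_imp),
        "cs": cosine_similarity_metric(d_orig, d_imp),
    }
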