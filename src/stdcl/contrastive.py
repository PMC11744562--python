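"""View corruption and the two contrastive losses.

The corrupted view multiplies the processed expression elementwise by
Gaussian noise (Hadamard product), so a noise mean of 1 preserves expected
expression.  Two losses act on the resulting pair of embeddings:

* space-aware contrastive loss — MSE between the n x n cross-view cosine
  similarity matrix S and the fused adjacency A, pulling spatially adjacent
  spots together and pushing non-adjacent spots apart;
* cluster-level feature contrastive loss — spots are partitioned into k
  near-equal groups, group-mean embeddings are read out per view, and the
  d x d cross-view *feature* cosine matrix is pushed toward the identity,
  decorrelating latent dimensions.

The total objective weights the three components:
``L = gamma1 * L_rec + gamma2 * L_con + gamma3 * L_clu``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import LossWeights

__all__ = [
    "NoiseSpec",
    "GroupAssignment",
    "corrupt_expression",
    "cross_view_similarity",
    "space_contrastive_loss",
    "assign_groups",
    "cluster_readout",
    "cluster_feature_loss",
    "total_loss",
]


@dataclass
class NoiseSpec:
    """Parameters of the multiplicative Gaussian corruption."""

    mean: float = 1.0
    std: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.std <= 0:
            raise ValueError(f"noise std must be positive, got {self.std}")


@dataclass
class GroupAssignment:
    """Partition of spots into k groups for the cluster-level readout."""

    groups: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.groups = np.asarray(self.groups, dtype=int)
        counts = np.bincount(self.groups, minlength=self.k)
        if self.groups.min(initial=0) < 0 or self.groups.max(initial=0) >= self.k:
            raise ValueError("group labels must lie in [0, k)")
        if np.any(counts == 0):
            raise ValueError("every group must be non-empty")


def corrupt_expression(
    X: np.ndarray,
    noise: NoiseSpec,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Hadamard-product corruption ``X * N`` with ``N ~ Normal(mean, std^2)``.

    With ``rng=None`` a fresh generator is seeded from ``noise.seed`` so the
    same spec always yields the same corruption; the training loop passes a
    persistent generator to draw fresh noise each epoch deterministically.
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    return X * rng.normal(noise.mean, noise.std, size=X.shape)


def cross_view_similarity(Z: np.ndarray, Z_hat: np.ndarray) -> np.ndarray:
    """Cross-view cosine similarity ``S_ij = cos(Z_i, Z_hat_j)``.

    Zero-norm rows yield similarity 0 for the affected pairs (with a
    warning) rather than NaN.
    """
    if Z.shape != Z_hat.shape:
        raise ValueError(f"shape mismatch: {Z.shape} vs {Z_hat.shape}")
    nz = np.linalg.norm(Z, axis=1)
    nzh = np.linalg.norm(Z_hat, axis=1)
    if np.any(nz == 0) or np.any(nzh == 0):
        warnings.warn("zero-norm embedding rows: similarity set to 0 for them")
    Zn = np.divide(Z, nz[:, None], out=np.zeros_like(Z, dtype=float), where=nz[:, None] > 0)
    Zhn = np.divide(
        Z_hat, nzh[:, None], out=np.zeros_like(Z_hat, dtype=float), where=nzh[:, None] > 0
    )
    return Zn @ Zhn.T


def space_contrastive_loss(S: np.ndarray, A: np.ndarray) -> float:
    """Mean squared difference between similarity matrix and adjacency."""
    if S.shape != A.shape:
        raise ValueError(f"shape mismatch: {S.shape} vs {A.shape}")
    return float(np.mean((S - A) ** 2))


def assign_groups(n: int, k: int, seed: int = 0) -> GroupAssignment:
    """Seeded random partition of ``n`` spots into ``k`` near-equal groups."""
    if k > n:
        raise ValueError(f"k={k} groups cannot exceed n={n} spots")
    perm = np.random.default_rng(seed).permutation(n)
    groups = np.empty(n, dtype=int)
    # first n % k groups get one extra member
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    start = 0
    for g, s in enumerate(sizes):
        groups[perm[start : start + s]] = g
        start += s
    return GroupAssignment(groups=groups, k=k)


def cluster_readout(Z: np.ndarray, g: GroupAssignment) -> np.ndarray:
    """Group-mean readout: row i is the mean of Z rows assigned to group i."""
    if len(g.groups) != Z.shape[0]:
        raise ValueError("group assignment length does not match embedding rows")
    counts = np.bincount(g.groups, minlength=g.k).astype(float)
    if np.any(counts == 0):
        raise ValueError("empty group in readout")
    R = np.zeros((g.k, Z.shape[1]))
    np.add.at(R, g.groups, Z)
    return R / counts[:, None]


def _feature_cosine(R1: np.ndarray, R2: np.ndarray, eps: float = 0.0) -> np.ndarray:
    n1 = np.linalg.norm(R1, axis=0)
    n2 = np.linalg.norm(R2, axis=0)
    if np.any(n1 == 0) or np.any(n2 == 0):
        raise ValueError("all-zero readout feature column")
    return (R1.T @ R2) / np.outer(n1, n2)


def cluster_feature_loss(
    R1: np.ndarray, R2: np.ndarray, uniform: bool = False
) -> float:
    """Push the d x d cross-view feature cosine matrix toward the identity.

    Feature vectors are the *columns* of the k x d readout matrices.  The
    default split normalization divides the diagonal term by d^2 and the
    off-diagonal term by d^2 - d; ``uniform=True`` divides everything by
    d^2 instead.
    """
    if R1.shape != R2.shape:
        raise ValueError(f"shape mismatch: {R1.shape} vs {R2.shape}")
    d = R1.shape[1]
    if d < 2:
        raise ValueError("cluster feature loss requires latent dimension >= 2")
    S = _feature_cosine(R1, R2)
    diag = np.diag(S)
    off = S - np.diag(diag)
    if uniform:
        return float((np.sum((diag - 1.0) ** 2) + np.sum(off**2)) / d**2)
    return float(
        np.sum((diag - 1.0) ** 2) / d**2 + np.sum(off**2) / (d**2 - d)
    )


def total_loss(l_rec: float, l_con: float, l_clu: float, w: LossWeights | None = None) -> float:
    """Weighted sum ``gamma1*L_rec + gamma2*L_con + gamma3*L_clu``."""
    w = w or LossWeights()
    return w.gamma1 * l_rec + w.gamma2 * l_con + w.gamma3 * l_clu
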