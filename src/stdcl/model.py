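"""Single-hidden-layer graph convolutional autoencoder.

The encoder and decoder are each one graph-convolution layer sharing the
propagation matrix ``A_norm = D^{-1/2}(A + I)D^{-1/2}``:

    Z = act(A_norm @ X @ W_e)          latent embedding, n x d
    H = A_norm @ Z @ W_d               reconstructed expression, n x g
    A_hat = sigmoid(Z @ Z.T)           inner-product adjacency decoder

The encoder activation defaults to ELU; the decoder is linear because the
input expression is zero-mean scaled, which a bounded or non-negative
activation could not reconstruct.  The reconstruction loss balances the
expression and adjacency residuals:

    L_rec = (1/n) * sum_i [ alpha1 ||H_i - X_i||^2 + alpha2 ||A_hat_i - A_i||^2 ]

with defaults (alpha1, alpha2) = (1.0, 0.5).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal

import numpy as np

__all__ = [
    "ModelState",
    "ForwardOutputs",
    "LossWeights",
    "init_model",
    "encode",
    "decode",
    "reconstruct_adjacency",
    "reconstruction_loss",
    "save_checkpoint",
    "load_checkpoint",
]

Activation = Literal["relu", "elu", "identity"]


def _relu(u: np.ndarray) -> np.ndarray:
    return np.maximum(u, 0.0)


def _drelu(u: np.ndarray) -> np.ndarray:
    return (u > 0).astype(float)


def _elu(u: np.ndarray) -> np.ndarray:
    return np.where(u > 0, u, np.expm1(np.minimum(u, 0.0)))


def _delu(u: np.ndarray) -> np.ndarray:
    return np.where(u > 0, 1.0, np.exp(np.minimum(u, 0.0)))


def _identity(u: np.ndarray) -> np.ndarray:
    return u


def _didentity(u: np.ndarray) -> np.ndarray:
    return np.ones_like(u)


ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "relu": (_relu, _drelu),
    "elu": (_elu, _delu),
    "identity": (_identity, _didentity),
}


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class LossWeights:
    """Weights of the composite objective.

    ``alpha1``/``alpha2`` balance expression vs adjacency reconstruction;
    ``gamma1``/``gamma2``/``gamma3`` weight the reconstruction, space-aware
    contrastive and cluster-level feature contrastive losses in the total
    objective.  Defaults (10, 0.5, 0.8) and (1.0, 0.5).
    """

    gamma1: float = 10.0
    gamma2: float = 0.5
    gamma3: float = 0.8
    alpha1: float = 1.0
    alpha2: float = 0.5

    def __post_init__(self) -> None:
        vals = (self.gamma1, self.gamma2, self.gamma3, self.alpha1, self.alpha2)
        if any(v < 0 for v in vals):
            raise ValueError("loss weights must be non-negative")
        if all(v == 0 for v in vals):
            raise ValueError("at least one loss weight must be positive")


@dataclass
class ModelState:
    """Encoder/decoder weights and architecture choices."""

    W_e: np.ndarray
    W_d: np.ndarray
    d: int
    activation: Activation = "elu"
    decoder_activation: Activation = "identity"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.W_e)) and np.all(np.isfinite(self.W_d))):
            raise ValueError("model weights must be finite")
        n_hvg = self.W_e.shape[0]
        if self.W_e.shape != (n_hvg, self.d) or self.W_d.shape != (self.d, n_hvg):
            raise ValueError(
                f"inconsistent shapes: W_e {self.W_e.shape}, W_d {self.W_d.shape}, d={self.d}"
            )

    def copy(self) -> "ModelState":
        return ModelState(
            self.W_e.copy(),
            self.W_d.copy(),
            self.d,
            self.activation,
            self.decoder_activation,
            self.rng_seed,
        )


@dataclass
class ForwardOutputs:
    """Outputs of one forward pass over both views."""

    Z: np.ndarray
    Z_hat: np.ndarray | None
    H: np.ndarray
    A_hat: np.ndarray = field(repr=False)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_model(
    n_hvg: int,
    d: int = 64,
    seed: int = 0,
    activation: Activation = "elu",
    decoder_activation: Activation = "identity",
) -> ModelState:
    """Glorot-uniform initialization; identical seeds give identical weights."""
    if d < 2:
        raise ValueError(f"latent dimension must be >= 2, got {d}")
    rng = np.random.default_rng(seed)
    W_e = _glorot(rng, n_hvg, d)
    W_d = _glorot(rng, d, n_hvg)
    return ModelState(W_e, W_d, d, activation, decoder_activation, seed)


def encode(X: np.ndarray, A_norm: np.ndarray, model: ModelState) -> np.ndarray:
    """One graph convolution: ``act(A_norm @ X @ W_e)``."""
    if not np.all(np.isfinite(X)):
        raise ValueError("encode input contains non-finite values")
    act = ACTIVATIONS[model.activation][0]
    return act(A_norm @ X @ model.W_e)


def decode(Z: np.ndarray, A_norm: np.ndarray, model: ModelState) -> np.ndarray:
    """Decoder graph convolution: ``act_d(A_norm @ Z @ W_d)``; linear by default."""
    if not np.all(np.isfinite(Z)):
        raise ValueError("decode input contains non-finite values")
    act = ACTIVATIONS[model.decoder_activation][0]
    return act(A_norm @ Z @ model.W_d)


def reconstruct_adjacency(Z: np.ndarray) -> np.ndarray:
    """Inner-product decoder ``sigmoid(Z @ Z.T)``; symmetric, entries in (0, 1)."""
    return sigmoid(Z @ Z.T)


def reconstruction_loss(
    X: np.ndarray,
    H: np.ndarray,
    A: np.ndarray,
    A_hat: np.ndarray,
    w: LossWeights | None = None,
) -> float:
    """Per-spot weighted sum of squared expression and adjacency residuals."""
    w = w or LossWeights()
    if H.shape != X.shape or A_hat.shape != A.shape:
        raise ValueError("shape mismatch in reconstruction loss")
    n = X.shape[0]
    expr = np.sum((H - X) ** 2)
    adj = np.sum((A_hat - A) ** 2)
    return float((w.alpha1 * expr + w.alpha2 * adj) / n)


def save_checkpoint(model: ModelState, path: str | os.PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(
        path,
        W_e=model.W_e,
        W_d=model.W_d,
        d=model.d,
        activation=model.activation,
        decoder_activation=model.decoder_activation,
        rng_seed=model.rng_seed,
    )
    return path


def load_checkpoint(path: str | os.PathLike) -> ModelState:
    with np.load(path, allow_pickle=False) as f:
        return ModelState(
            f["W_e"],
            f["W_d"],
            int(f["d"]),
            str(f["activation"]),
            str(f["decoder_activation"]),
            int(f["rng_seed"]),
        )
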