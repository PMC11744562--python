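"""Canonical default configuration of the pipeline.

Every documented default lives in :data:`DEFAULTS` so that configuration
files, the CLI and the library share one source of truth.  A flat
key–value YAML file can override any entry.
"""

from __future__ import annotations

import os
from types import MappingProxyType

__all__ = ["DEFAULTS", "load_config"]

DEFAULTS = MappingProxyType(
    {
        # preprocessing
        "n_hvg": 3000,
        "hvg_statistic": "dispersion",
        # graph construction
        "k_spatial": 3,
        "k_gene": 3,
        "alpha": 0.5,
        "metric": "euclidean",
        "expr_pcs": 50,
        # model
        "latent_dim": 64,
        "activation": "elu",
        "decoder_activation": "identity",
        # loss weights
        "alpha1": 1.0,
        "alpha2": 0.5,
        "gamma1": 10.0,
        "gamma2": 0.5,
        "gamma3": 0.8,
        # corruption noise (two runs, selected by Davies-Bouldin)
        "noise_mean": 1.0,
        "noise_stds": (0.1, 0.2),
        # optimization schedule
        "pretrain_epochs": 500,
        "train_epochs": 1000,
        "pretrain_lr": 0.001,
        "train_lr": 0.005,
        "optimizer": "adam",
        # clustering and refinement
        "pca_components": 20,
        "gmm_covariance": "shared",
        "leiden_resolution": 1.0,
        "refine_radius": 50.0,
        # denoising and gene ranking
        "denoise_neighbors": 15,
        "top_genes": 1000,
    }
)


def load_config(path: str | os.PathLike | None = None) -> dict:
    """Return the defaults, overridden by a flat YAML file if given."""
    cfg = dict(DEFAULTS)
    if path is not None:
        import yaml

        with open(path) as f:
            user = yaml.safe_load(f) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg
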