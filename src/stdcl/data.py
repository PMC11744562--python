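"""Input containers and the normalization / feature-selection pipeline.

A :class:`SpatialDataset` holds a spots × genes count matrix together with
2-D spatial coordinates and optional ground-truth domain labels.  The
preprocessing pipeline mirrors the standard single-cell recipe: library-size
normalization to the median total count, ``log1p``, highly-variable-gene
selection, and per-gene scaling to zero mean / unit variance.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "SpatialDataset",
    "ProcessedExpression",
    "load_dataset",
    "write_dataset",
    "normalize_log",
    "select_hvg",
    "scale_features",
    "preprocess",
]


@dataclass
class SpatialDataset:
    """A spot/cell × gene expression matrix with spatial coordinates.

    Attributes
    ----------
    counts
        Non-negative expression matrix, shape ``(n_spots, n_genes)``.
    spot_ids, gene_ids
        Unique identifiers for rows and columns of ``counts``.
    coords
        2-D spatial coordinates, shape ``(n_spots, 2)``, in platform units.
    labels
        Optional integer ground-truth domain labels, length ``n_spots``.
    """

    counts: np.ndarray
    spot_ids: list[str]
    gene_ids: list[str]
    coords: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.spot_ids = [str(s) for s in self.spot_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
        self.validate()

    def validate(self) -> None:
        n, g = self.counts.shape
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts contains NaN or Inf")
        if np.any(self.counts < 0):
            raise ValueError("counts contains negative entries")
        if len(self.spot_ids) != n:
            raise ValueError(f"{len(self.spot_ids)} spot_ids for {n} spots")
        if len(self.gene_ids) != g:
            raise ValueError(f"{len(self.gene_ids)} gene_ids for {g} genes")
        if len(set(self.spot_ids)) != n:
            raise ValueError("spot_ids are not unique")
        if len(set(self.gene_ids)) != g:
            raise ValueError("gene_ids are not unique")
        if self.coords.shape != (n, 2):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match {n} spots"
            )
        if self.labels is not None and len(self.labels) != n:
            raise ValueError("labels length does not match number of spots")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def to_anndata(self) -> ad.AnnData:
        adata = ad.AnnData(
            X=self.counts.copy(),
            obs=pd.DataFrame(index=self.spot_ids),
            var=pd.DataFrame(index=self.gene_ids),
        )
        adata.obsm["spatial"] = self.coords.copy()
        if self.labels is not None:
            adata.obs["ground_truth"] = self.labels
        return adata


@dataclass
class ProcessedExpression:
    """HVG-subset, scaled expression ready for the model.

    ``X`` has zero-mean, unit-variance columns (constant columns are all
    zero); ``hvg_indices`` index into the parent gene axis; ``scaling_stats``
    records the per-gene mean and variance used for scaling.
    """

    X: np.ndarray
    hvg_indices: np.ndarray
    scaling_stats: pd.DataFrame = field(repr=False)

    @property
    def n_hvg(self) -> int:
        return self.X.shape[1]


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

_MTX_MATRIX = "matrix.mtx"
_MTX_GENES = "genes.tsv"
_MTX_BARCODES = "barcodes.tsv"
_MTX_POSITIONS = "positions.csv"


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required file not found: {path}")
    return path


def load_dataset(
    path: str | os.PathLike,
    format: Literal["mtx_dir", "h5ad", "csv"] = "mtx_dir",
) -> SpatialDataset:
    """Load a spatial dataset from disk.

    The returned counts matrix is always oriented spots × genes, regardless
    of the on-disk orientation of the MTX file.
    """
    path = Path(path)
    _require(path)
    if format == "mtx_dir":
        return _load_mtx_dir(path)
    if format == "h5ad":
        return _load_h5ad(path)
    if format == "csv":
        return _load_csv_dir(path)
    raise ValueError(f"unknown format: {format!r}")


def _load_mtx_dir(path: Path) -> SpatialDataset:
    mat = scipy.io.mmread(_require(path / _MTX_MATRIX))
    genes = pd.read_csv(_require(path / _MTX_GENES), sep="\t", header=None)
    barcodes = pd.read_csv(_require(path / _MTX_BARCODES), sep="\t", header=None)
    positions = pd.read_csv(_require(path / _MTX_POSITIONS))
    gene_ids = genes.iloc[:, 0].astype(str).tolist()
    spot_ids = barcodes.iloc[:, 0].astype(str).tolist()
    counts = np.asarray(mat.todense() if sp.issparse(mat) else mat, dtype=float)
    if counts.shape == (len(gene_ids), len(spot_ids)) and counts.shape[0] != counts.shape[1]:
        counts = counts.T  # on-disk genes × spots (CellRanger convention)
    if counts.shape != (len(spot_ids), len(gene_ids)):
        raise ValueError(
            f"matrix shape {counts.shape} matches neither orientation of "
            f"{len(spot_ids)} spots x {len(gene_ids)} genes"
        )
    pos = positions.set_index(positions.columns[0])
    missing = [s for s in spot_ids if s not in pos.index]
    if missing or len(pos) != len(spot_ids):
        raise ValueError(
            f"coordinate file has {len(pos)} rows for {len(spot_ids)} spots"
            + (f"; missing ids e.g. {missing[:3]}" if missing else "")
        )
    coords = pos.loc[spot_ids, ["x", "y"]].to_numpy(dtype=float)
    labels = None
    truth = path / "truth.tsv"
    if truth.exists():
        tdf = pd.read_csv(truth, sep="\t").set_index("spot_id")
        labels = tdf.loc[spot_ids, "label"].to_numpy(dtype=int)
    return SpatialDataset(counts, spot_ids, gene_ids, coords, labels)


def _load_h5ad(path: Path) -> SpatialDataset:
    adata = ad.read_h5ad(path)
    X = adata.X
    counts = np.asarray(X.todense() if sp.issparse(X) else X, dtype=float)
    if "spatial" not in adata.obsm:
        raise ValueError("h5ad file has no obsm['spatial'] coordinate array")
    labels = None
    if "ground_truth" in adata.obs:
        labels = adata.obs["ground_truth"].to_numpy(dtype=int)
    return SpatialDataset(
        counts,
        adata.obs_names.tolist(),
        adata.var_names.tolist(),
        np.asarray(adata.obsm["spatial"], dtype=float),
        labels,
    )


def _load_csv_dir(path: Path) -> SpatialDataset:
    counts_df = pd.read_csv(_require(path / "counts.csv"), index_col=0)
    pos = pd.read_csv(_require(path / _MTX_POSITIONS)).set_index("spot_id")
    spot_ids = counts_df.index.astype(str).tolist()
    if len(pos) != len(spot_ids):
        raise ValueError(
            f"coordinate file has {len(pos)} rows for {len(spot_ids)} spots"
        )
    coords = pos.loc[spot_ids, ["x", "y"]].to_numpy(dtype=float)
    labels = None
    truth = path / "truth.tsv"
    if truth.exists():
        tdf = pd.read_csv(truth, sep="\t").set_index("spot_id")
        labels = tdf.loc[spot_ids, "label"].to_numpy(dtype=int)
    return SpatialDataset(
        counts_df.to_numpy(dtype=float),
        spot_ids,
        counts_df.columns.astype(str).tolist(),
        coords,
        labels,
    )


def write_dataset(
    ds: SpatialDataset,
    path: str | os.PathLike,
    format: Literal["mtx_dir", "h5ad", "csv"] = "mtx_dir",
) -> Path:
    """Write a dataset to disk in one of the supported formats."""
    path = Path(path)
    if format == "h5ad":
        path.parent.mkdir(parents=True, exist_ok=True)
        ds.to_anndata().write_h5ad(path)
        return path
    path.mkdir(parents=True, exist_ok=True)
    positions = pd.DataFrame(
        {"spot_id": ds.spot_ids, "x": ds.coords[:, 0], "y": ds.coords[:, 1]}
    )
    positions.to_csv(path / _MTX_POSITIONS, index=False)
    if ds.labels is not None:
        pd.DataFrame({"spot_id": ds.spot_ids, "label": ds.labels}).to_csv(
            path / "truth.tsv", sep="\t", index=False
        )
    if format == "mtx_dir":
        # genes x spots on disk, the CellRanger convention
        scipy.io.mmwrite(path / _MTX_MATRIX, sp.csr_matrix(ds.counts.T))
        pd.Series(ds.gene_ids).to_csv(
            path / _MTX_GENES, sep="\t", index=False, header=False
        )
        pd.Series(ds.spot_ids).to_csv(
            path / _MTX_BARCODES, sep="\t", index=False, header=False
        )
    elif format == "csv":
        pd.DataFrame(ds.counts, index=ds.spot_ids, columns=ds.gene_ids).to_csv(
            path / "counts.csv"
        )
    else:
        raise ValueError(f"unknown format: {format!r}")
    return path


# ---------------------------------------------------------------------------
# Normalization / HVG / scaling
# ---------------------------------------------------------------------------


def normalize_log(
    ds: SpatialDataset, target_sum: float | None = None
) -> np.ndarray:
    """Library-size normalize each spot, then apply ``log(1 + x)``.

    Every spot is rescaled so its total count equals ``target_sum`` (default:
    the median total count of the dataset), after which ``log1p`` is applied
    elementwise.  Spots with zero total count cannot be normalized and raise
    a :class:`ValueError` naming the offending spot ids.
    """
    counts = ds.counts
    totals = counts.sum(axis=1)
    zero = totals == 0
    if np.any(zero):
        bad = [ds.spot_ids[i] for i in np.flatnonzero(zero)[:10]]
        raise ValueError(f"all-zero spots cannot be normalized: {bad}")
    if target_sum is None:
        target_sum = float(np.median(totals))
    return np.log1p(counts * (target_sum / totals)[:, None])


def select_hvg(
    Xn: np.ndarray,
    n_top: int = 3000,
    statistic: Literal["dispersion", "variance"] = "dispersion",
) -> np.ndarray:
    """Indices of the ``n_top`` most variable genes of a log-normalized matrix.

    ``dispersion`` uses the Seurat-flavored normalized-dispersion statistic
    (binned mean/dispersion z-scores, as in scanpy); ``variance`` ranks by
    plain per-gene variance.  Datasets with at most ``n_top`` genes keep all
    genes — the convention for gene-panel platforms (STARmap, osmFISH,
    MERFISH) where no selection is performed.
    """
    if n_top <= 0:
        raise ValueError(f"n_top must be positive, got {n_top}")
    n_genes = Xn.shape[1]
    if n_genes <= n_top:
        return np.arange(n_genes)
    if statistic == "variance":
        var = Xn.var(axis=0)
        order = np.argsort(-var, kind="stable")
        return np.sort(order[:n_top])
    if statistic != "dispersion":
        raise ValueError(f"unknown statistic: {statistic!r}")
    import scanpy as sc

    adata = ad.AnnData(X=Xn.copy())
    sc.pp.highly_variable_genes(adata, n_top_genes=n_top, flavor="seurat")
    return np.flatnonzero(adata.var["highly_variable"].to_numpy())


def scale_features(Xn: np.ndarray, hvg: Sequence[int]) -> ProcessedExpression:
    """Subset to HVGs and scale each gene to zero mean / unit variance.

    Constant genes (zero variance) become all-zero columns rather than NaN.
    No clipping is applied.
    """
    hvg = np.asarray(hvg, dtype=int)
    if hvg.size == 0:
        raise ValueError("hvg index list is empty")
    sub = Xn[:, hvg]
    mean = sub.mean(axis=0)
    var = sub.var(axis=0)
    std = np.sqrt(var)
    safe = np.where(std > 0, std, 1.0)
    X = (sub - mean) / safe
    X[:, std == 0] = 0.0
    stats = pd.DataFrame({"gene_index": hvg, "mean": mean, "variance": var})
    return ProcessedExpression(X=X, hvg_indices=hvg, scaling_stats=stats)


def preprocess(
    ds: SpatialDataset,
    n_hvg: int = 3000,
    target_sum: float | None = None,
    hvg_statistic: Literal["dispersion", "variance"] = "dispersion",
) -> ProcessedExpression:
    """Full pipeline: normalize → log1p → HVG selection → scaling."""
    Xn = normalize_log(ds, target_sum=target_sum)
    hvg = select_hvg(Xn, n_top=n_hvg, statistic=hvg_statistic)
    return scale_features(Xn, hvg)
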