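"""IO round-trips, validation, normalization, HVG selection and scaling."""

import numpy as np
import pytest

from stdcl.data import (
    SpatialDataset,
    load_dataset,
    normalize_log,
    preprocess,
    scale_features,
    select_hvg,
    write_dataset,
)


class TestSpatialDataset:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="negative"):
            SpatialDataset(-np.ones((2, 2)), ["a", "b"], ["g", "h"], np.zeros((2, 2)))
        with pytest.raises(ValueError, match="unique"):
            SpatialDataset(np.ones((2, 2)), ["a", "a"], ["g", "h"], np.zeros((2, 2)))
        with pytest.raises(ValueError, match="coords"):
            SpatialDataset(np.ones((3, 2)), list("abc"), ["g", "h"], np.zeros((2, 2)))
        with pytest.raises(ValueError, match="NaN"):
            SpatialDataset(
                np.array([[1.0, np.nan]]), ["a"], ["g", "h"], np.zeros((1, 2))
            )


class TestIO:
    @pytest.mark.parametrize("fmt", ["mtx_dir", "csv", "h5ad"])
    def test_write_load_round_trip(self, small_tissue, tmp_path, fmt):
        target = tmp_path / "ds.h5ad" if fmt == "h5ad" else tmp_path / "ds"
        write_dataset(small_tissue, target, format=fmt)
        back = load_dataset(target, format=fmt)
        np.testing.assert_array_equal(back.counts, small_tissue.counts)
        np.testing.assert_allclose(back.coords, small_tissue.coords, atol=1e-9)
        assert back.spot_ids == small_tissue.spot_ids
        assert back.gene_ids == small_tissue.gene_ids
        np.testing.assert_array_equal(back.labels, small_tissue.labels)

    def test_csv_round_trip_tiny(self, tiny_dataset, tmp_path):
        write_dataset(tiny_dataset, tmp_path / "d", format="csv")
        back = load_dataset(tmp_path / "d", format="csv")
        assert back.counts.shape == (3, 2)
        np.testing.assert_allclose(back.coords, tiny_dataset.coords)

    def test_missing_file_named_in_error(self, tmp_path):
        (tmp_path / "d").mkdir()
        with pytest.raises(FileNotFoundError, match="matrix.mtx"):
            load_dataset(tmp_path / "d", format="mtx_dir")

    def test_coordinate_dimension_mismatch_rejected(self, tiny_dataset, tmp_path):
        write_dataset(tiny_dataset, tmp_path / "d", format="csv")
        pos = (tmp_path / "d" / "positions.csv").read_text().splitlines()
        (tmp_path / "d" / "positions.csv").write_text("\n".join(pos[:-1]) + "\n")
        with pytest.raises(ValueError, match="coordinate"):
            load_dataset(tmp_path / "d", format="csv")


class TestNormalizeLog:
    def test_equal_rows_stay_symmetric(self):
        ds = SpatialDataset(
            np.array([[1.0, 1.0], [2.0, 2.0]]), ["a", "b"], ["g", "h"],
            np.zeros((2, 2)),
        )
        out = normalize_log(ds)
        np.testing.assert_allclose(out[0], out[1])

    def test_row_sums_equal_after_normalization(self, rng):
        counts = rng.poisson(5.0, size=(10, 5)) + 1.0
        ds = SpatialDataset(
            counts, [f"s{i}" for i in range(10)], [f"g{j}" for j in range(5)],
            np.zeros((10, 2)),
        )
        pre_log = np.expm1(normalize_log(ds))
        sums = pre_log.sum(axis=1)
        np.testing.assert_allclose(sums, sums[0], rtol=1e-9)

    def test_single_spot_is_identity_up_to_target(self):
        ds = SpatialDataset(
            np.array([[2.0, 4.0]]), ["a"], ["g", "h"], np.zeros((1, 2))
        )
        np.testing.assert_allclose(normalize_log(ds), np.log1p([[2.0, 4.0]]))

    def test_all_zero_spot_lists_ids(self):
        ds = SpatialDataset(
            np.array([[1.0, 1.0], [0.0, 0.0]]), ["ok", "empty"], ["g", "h"],
            np.zeros((2, 2)),
        )
        with pytest.raises(ValueError, match="empty"):
            normalize_log(ds)

    def test_matches_scanpy_normalize_total(self, small_tissue):
        import anndata as adm
        import scanpy as sc

        ours = normalize_log(small_tissue)
        adata = adm.AnnData(X=small_tissue.counts.copy())
        sc.pp.normalize_total(adata)  # default: median of totals
        sc.pp.log1p(adata)
        np.testing.assert_allclose(ours, adata.X, atol=1e-9)


class TestSelectHVG:
    def test_small_panel_keeps_all_genes(self, rng):
        Xn = rng.random((20, 5))
        np.testing.assert_array_equal(select_hvg(Xn, n_top=5), np.arange(5))
        np.testing.assert_array_equal(select_hvg(Xn, n_top=3000), np.arange(5))

    def test_constant_gene_excluded(self, rng):
        Xn = rng.random((30, 6))
        Xn[:, 2] = 5.0
        idx = select_hvg(Xn, n_top=5, statistic="variance")
        assert 2 not in idx

    def test_invalid_n_top(self, rng):
        with pytest.raises(ValueError):
            select_hvg(rng.random((5, 5)), n_top=0)

    def test_dispersion_flavor_selects_requested_count(self, rng):
        Xn = np.log1p(rng.poisson(3.0, size=(60, 40)).astype(float))
        idx = select_hvg(Xn, n_top=10, statistic="dispersion")
        assert len(idx) == 10
        assert len(np.unique(idx)) == 10


class TestScaleFeatures:
    def test_column_mean_zero_variance_one(self):
        out = scale_features(np.array([[1.0], [2.0], [3.0]]), [0])
        assert out.X[:, 0].mean() == pytest.approx(0.0, abs=1e-12)
        assert out.X[:, 0].var() == pytest.approx(1.0, abs=1e-12)

    def test_constant_column_becomes_zero(self):
        out = scale_features(np.array([[5.0], [5.0], [5.0]]), [0])
        np.testing.assert_array_equal(out.X, np.zeros((3, 1)))

    def test_random_matrix_statistics(self, rng):
        Xn = rng.random((50, 10))
        out = scale_features(Xn, np.arange(10))
        np.testing.assert_allclose(out.X.mean(axis=0), 0.0, atol=1e-6)
        np.testing.assert_allclose(out.X.var(axis=0), 1.0, atol=1e-6)
        assert out.n_hvg == 10

    def test_empty_hvg_rejected(self, rng):
        with pytest.raises(ValueError):
            scale_features(rng.random((5, 5)), [])


def test_preprocess_is_deterministic(small_tissue):
    a = preprocess(small_tissue, n_hvg=30)
    b = preprocess(small_tissue, n_hvg=30)
    np.testing.assert_array_equal(a.X, b.X)
    np.testing.assert_array_equal(a.hvg_indices, b.hvg_indices)
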