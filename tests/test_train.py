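"""Optimization correctness, clustering, run selection and refinement."""

import numpy as np
import pytest
import scipy.sparse as sp

from stdcl.contrastive import NoiseSpec, assign_groups
from stdcl.graph import build_graph
from stdcl.model import LossWeights, init_model
from stdcl.train import (
    ClusteringResult,
    RefineConfig,
    TrainConfig,
    _loss_and_grads,
    cluster_embedding,
    pretrain,
    reduce_pca,
    refine_labels,
    select_run_by_dbi,
    train,
)


@pytest.fixture(scope="module")
def small_instance():
    rng = np.random.default_rng(3)
    n, g, d = 30, 12, 6
    coords = rng.normal(size=(n, 2))
    X = rng.normal(size=(n, g))
    graph = build_graph(coords, X, expr_pcs=None)
    model = init_model(g, d, seed=0)
    return X, graph, model


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        n, g, d = 7, 5, 4
        X = rng.normal(size=(n, g))
        X_hat = X * rng.normal(1, 0.1, size=(n, g))
        graph = build_graph(rng.normal(size=(n, 2)), X, k1=2, k2=2, expr_pcs=None)
        M = sp.csr_matrix(graph.A_norm)
        P = np.asarray(M @ X)
        model = init_model(g, d, seed=1)
        w = LossWeights()
        groups = assign_groups(n, 3, seed=0)
        _, dWe, dWd, _ = _loss_and_grads(
            model, X, graph.A, M, P, w, X_hat=X_hat, groups=groups
        )

        def total(We, Wd):
            m = model.copy()
            m.W_e, m.W_d = We, Wd
            losses, _, _, _ = _loss_and_grads(
                m, X, graph.A, M, P, w, X_hat=X_hat, groups=groups
            )
            return losses["total"]

        eps = 1e-6
        for (analytic, W, setter) in [
            (dWe, model.W_e, "W_e"),
            (dWd, model.W_d, "W_d"),
        ]:
            idx = [(0, 0), (1, 2), (W.shape[0] - 1, W.shape[1] - 1)]
            for i, j in idx:
                Wp, Wm = W.copy(), W.copy()
                Wp[i, j] += eps
                Wm[i, j] -= eps
                if setter == "W_e":
                    num = (total(Wp, model.W_d) - total(Wm, model.W_d)) / (2 * eps)
                else:
                    num = (total(model.W_e, Wp) - total(model.W_e, Wm)) / (2 * eps)
                assert analytic[i, j] == pytest.approx(num, abs=1e-6)

    def test_single_plain_gradient_step_reduces_reconstruction(self):
        # linear toy instance, tiny step on the reconstruction objective
        rng = np.random.default_rng(5)
        n, g, d = 6, 4, 3
        X = rng.normal(size=(n, g))
        graph = build_graph(rng.normal(size=(n, 2)), X, k1=2, k2=2, expr_pcs=None)
        M = sp.csr_matrix(graph.A_norm)
        P = np.asarray(M @ X)
        model = init_model(g, d, seed=2, activation="identity")
        w = LossWeights()
        l0, dWe, dWd, _ = _loss_and_grads(model, X, graph.A, M, P, w)
        model.W_e -= 1e-4 * dWe
        model.W_d -= 1e-4 * dWd
        l1, _, _, _ = _loss_and_grads(model, X, graph.A, M, P, w)
        assert l1["l_rec"] < l0["l_rec"]


class TestTrainingPhases:
    def test_zero_epochs_is_identity(self, small_instance):
        X, graph, model = small_instance
        cfg = TrainConfig(pretrain_epochs=0, train_epochs=0)
        out = pretrain(model, X, graph, cfg)
        np.testing.assert_array_equal(out.W_e, model.W_e)

    def test_pretrain_reduces_reconstruction_loss(self):
        rng = np.random.default_rng(11)
        n, g = 100, 20
        X = rng.normal(size=(n, g))
        graph = build_graph(rng.normal(size=(n, 2)), X, expr_pcs=None)
        model = init_model(g, 8, seed=0)
        cfg = TrainConfig(pretrain_epochs=50, train_epochs=0)
        M = sp.csr_matrix(graph.A_norm)
        P = np.asarray(M @ X)
        before, _, _, _ = _loss_and_grads(model, X, graph.A, M, P, LossWeights())
        trained = pretrain(model, X, graph, cfg)
        after, _, _, _ = _loss_and_grads(trained, X, graph.A, M, P, LossWeights())
        assert after["l_rec"] < before["l_rec"]

    def test_train_history_is_deterministic(self, small_instance):
        X, graph, model = small_instance
        cfg = TrainConfig(pretrain_epochs=0, train_epochs=10, seed=0)
        _, h1 = train(model, X, graph, k=3, cfg=cfg, noise=NoiseSpec(seed=1))
        _, h2 = train(model, X, graph, k=3, cfg=cfg, noise=NoiseSpec(seed=1))
        assert h1.equals(h2)

    def test_train_reduces_total_loss(self, small_instance):
        X, graph, model = small_instance
        cfg = TrainConfig(pretrain_epochs=20, train_epochs=60, seed=0)
        m = pretrain(model, X, graph, cfg)
        _, hist = train(m, X, graph, k=3, cfg=cfg, noise=NoiseSpec(seed=1))
        assert hist["total"].iloc[-1] < hist["total"].iloc[0]

    def test_default_schedule_matches_published(self):
        cfg = TrainConfig()
        assert (cfg.pretrain_epochs, cfg.train_epochs) == (500, 1000)
        assert (cfg.pretrain_lr, cfg.train_lr) == (0.001, 0.005)
        assert cfg.optimizer == "adam"


class TestReducePca:
    def test_full_rank_is_isometry(self, rng):
        Z = rng.normal(size=(20, 6))
        emb = reduce_pca(Z, n_comp=6)
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(Z), pdist(emb), atol=1e-9)

    def test_component_variance_non_increasing(self, rng):
        Z = rng.normal(size=(50, 10)) * np.arange(1, 11)
        emb = reduce_pca(Z, n_comp=8)
        var = emb.var(axis=0)
        assert np.all(np.diff(var) <= 1e-9)

    def test_n_comp_exceeding_dim_rejected(self, rng):
        with pytest.raises(ValueError):
            reduce_pca(rng.normal(size=(5, 3)), n_comp=4)

    def test_deterministic_sign_convention(self, rng):
        Z = rng.normal(size=(30, 5))
        np.testing.assert_array_equal(reduce_pca(Z, 3), reduce_pca(Z, 3))


class TestClusterEmbedding:
    def test_separated_blobs_recovered_exactly(self, rng):
        centers = np.array([[0.0, 0.0], [30.0, 0.0]])
        pts = np.vstack([rng.normal(c, 1.0, size=(25, 2)) for c in centers])
        truth = np.repeat([0, 1], 25)
        labels = cluster_embedding(pts, k=2, method="gmm", seed=0)
        from stdcl.metrics import adjusted_rand_index

        assert adjusted_rand_index(truth, labels) == pytest.approx(1.0)

    def test_k_equals_n_gives_singletons(self, rng):
        pts = rng.normal(size=(6, 2))
        np.testing.assert_array_equal(
            cluster_embedding(pts, k=6, method="gmm", seed=0), np.arange(6)
        )

    def test_seed_determinism(self, rng):
        pts = rng.normal(size=(40, 3))
        a = cluster_embedding(pts, k=3, seed=9)
        b = cluster_embedding(pts, k=3, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_leiden_runs_without_k(self, rng):
        pts = np.vstack(
            [rng.normal(0, 1, (20, 2)), rng.normal(20, 1, (20, 2))]
        )
        labels = cluster_embedding(pts, k=None, method="leiden", seed=0)
        assert len(labels) == 40 and labels.max() >= 1

    def test_k_exceeding_n_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_embedding(rng.normal(size=(4, 2)), k=5, method="gmm")


class TestRunSelection:
    def _result(self, dbi):
        return ClusteringResult(
            labels_raw=np.zeros(3, dtype=int),
            labels_refined=np.zeros(3, dtype=int),
            embedding_pca=np.zeros((3, 2)),
            dbi=dbi,
            noise_spec_used=NoiseSpec(),
            k=2,
        )

    def test_single_run_returned(self):
        r = self._result(0.7)
        assert select_run_by_dbi([r]) is r

    def test_minimum_dbi_selected(self):
        runs = [self._result(0.8), self._result(0.3)]
        assert select_run_by_dbi(runs) is runs[1]

    def test_tie_broken_by_order(self):
        runs = [self._result(0.5), self._result(0.5)]
        assert select_run_by_dbi(runs) is runs[0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_run_by_dbi([])


class TestRefineLabels:
    def test_mislabelled_spot_surrounded_by_majority(self):
        # center spot mislabelled, 6 same-labelled neighbors within radius
        coords = np.vstack([[0.0, 0.0], np.array([
            [1, 0], [-1, 0], [0, 1], [0, -1], [1, 1], [-1, -1]
        ], dtype=float)])
        labels = np.array([1, 0, 0, 0, 0, 0, 0])
        refined = refine_labels(labels, coords, RefineConfig(radius=2.0))
        assert refined[0] == 0

    def test_uniform_labels_are_fixed_point(self, rng):
        coords = rng.normal(size=(20, 2))
        labels = np.zeros(20, dtype=int)
        np.testing.assert_array_equal(
            refine_labels(labels, coords, RefineConfig(radius=1.0)), labels
        )

    def test_empty_neighborhood_keeps_label_with_warning(self):
        coords = np.array([[0.0, 0.0], [100.0, 100.0], [100.0, 101.0]])
        labels = np.array([2, 0, 0])
        with pytest.warns(UserWarning, match="empty"):
            refined = refine_labels(labels, coords, RefineConfig(radius=5.0))
        assert refined[0] == 2

    def test_never_increases_label_count(self, rng):
        coords = rng.uniform(0, 10, size=(60, 2))
        labels = rng.integers(0, 4, 60)
        refined = refine_labels(labels, coords, RefineConfig(radius=3.0))
        assert len(np.unique(refined)) <= len(np.unique(labels))

    def test_tie_keeps_original(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [-1.0, 0.0]])
        labels = np.array([2, 0, 1])  # neighbors split 1-1
        refined = refine_labels(labels, coords, RefineConfig(radius=1.5))
        assert refined[0] == 2
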