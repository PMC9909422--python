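"""Forward passes, DropNode, propagation, importance scores, estimator API."""

import numpy as np
import pytest

from hirand.io_graphs import build_sample_graph
from hirand.model import (HiRANDClassifier, drop_node,
                          forward_inference, forward_train,
                          gene_selection_forward, importance_scores,
                          init_params, mlp_forward, random_propagation)
from hirand.train import HiRANDConfig


class TestGeneSelectionForward:
    def test_identity_graph_identity_weight_is_elementwise_tanh(self, rng):
        X = rng.standard_normal((4, 3))
        H = gene_selection_forward(X, np.eye(3), np.eye(3), "tanh")
        np.testing.assert_allclose(H, np.tanh(X))

    def test_zero_weights_give_zero(self, rng):
        X = rng.standard_normal((4, 3))
        H = gene_selection_forward(X, np.ones((3, 3)), np.zeros((3, 3)))
        np.testing.assert_array_equal(H, np.zeros((4, 3)))

    def test_hand_matrix_arithmetic(self):
        X = np.array([[1.0, 0.0, 2.0], [0.5, 1.0, 0.0]])
        A = np.array([[1, 1, 0], [1, 1, 1], [0, 1, 1]], dtype=float)
        W = np.array([[0.1, 0.2, 0.3], [0.4, 0.5, 0.6], [0.7, 0.8, 0.9]])
        np.testing.assert_allclose(gene_selection_forward(X, A, W),
                                   np.tanh(X @ (A * W)), atol=1e-14)

    def test_shape_mismatch_errors(self, rng):
        with pytest.raises(ValueError, match="shape"):
            gene_selection_forward(rng.standard_normal((2, 4)), np.eye(3), np.eye(3))


class TestImportanceScores:
    def test_sum_to_one_and_nonnegative(self, rng):
        A = (rng.random((6, 6)) < 0.5).astype(float)
        A = np.maximum(A, A.T); np.fill_diagonal(A, 1)
        scores = importance_scores(rng.standard_normal((6, 6)), A).scores
        assert scores.sum() == pytest.approx(1.0)
        assert np.all(scores >= 0)

    def test_isolated_gene_scores_zero(self, rng):
        A = np.eye(3); A[2, 2] = 0  # gene 2 has no incident edge at all
        scores = importance_scores(rng.standard_normal((3, 3)), A).scores
        assert scores[2] == 0.0

    def test_matches_direct_loop_oracle(self):
        A = np.array([[1, 1, 0], [1, 1, 1], [0, 1, 1]], dtype=float)
        W = np.array([[0.5, -2.0, 9.9], [1.0, 0.25, -0.5], [9.9, 3.0, 0.1]])
        got = importance_scores(W, A).scores
        num = np.array([sum(A[i, j] * abs(W[i, j]) for i in range(3))
                        for j in range(3)])
        np.testing.assert_allclose(got, num / num.sum(), atol=1e-14)

    def test_sign_invariance(self, rng):
        A = np.ones((4, 4))
        W = rng.standard_normal((4, 4))
        np.testing.assert_allclose(importance_scores(W, A).scores,
                                   importance_scores(-W, A).scores)

    def test_all_zero_mass_errors(self):
        with pytest.raises(ValueError, match="importance undefined"):
            importance_scores(np.zeros((3, 3)), np.ones((3, 3)))


class TestDropNode:
    def test_delta_zero_identity(self, rng):
        H = rng.standard_normal((5, 3))
        np.testing.assert_array_equal(drop_node(H, 0.0, rng), H)

    def test_delta_one_zeroes_everything(self, rng):
        H = rng.standard_normal((5, 3))
        np.testing.assert_array_equal(drop_node(H, 1.0, rng), np.zeros_like(H))

    def test_expectation_matches_keep_probability(self, rng):
        H = rng.standard_normal((6, 4)) + 2.0
        delta = 0.3
        total = np.zeros_like(H)
        reps = 10_000
        for _ in range(reps):
            total += drop_node(H, delta, rng)
        mean = total / reps
        se = np.abs(H) * np.sqrt(delta * (1 - delta) / reps)
        assert np.all(np.abs(mean - (1 - delta) * H) < 3 * se + 1e-12)

    def test_rows_dropped_whole(self, rng):
        H = rng.standard_normal((50, 3)) + 5.0
        out = drop_node(H, 0.5, rng)
        zero_rows = np.all(out == 0, axis=1)
        kept_rows = np.all(out == H, axis=1)
        assert np.all(zero_rows | kept_rows)

    def test_scaled_variant_preserves_expectation_exactly(self, rng):
        H = np.ones((4, 2))
        out = drop_node(H, 0.5, np.random.default_rng(0), scale=True)
        assert set(np.unique(out)) <= {0.0, 2.0}

    def test_bad_delta(self, rng):
        with pytest.raises(ValueError):
            drop_node(np.ones((2, 2)), 1.5, rng)


class TestRandomPropagation:
    def test_identity_propagation_is_noop(self, rng):
        H = rng.standard_normal((6, 3))
        np.testing.assert_array_equal(random_propagation(H, np.eye(6), K=1), H)

    def test_K1_hand_computation(self, rng):
        X = rng.standard_normal((3, 4))
        SG = build_sample_graph(X, k=1)
        H = rng.standard_normal((3, 4))
        S = np.asarray(SG.similarity.todense())
        d = 1.0 / np.sqrt(S.sum(axis=1))
        Ahat = d[:, None] * S * d[None, :]
        np.testing.assert_allclose(random_propagation(H, SG, 1),
                                   (H + Ahat @ H) / 2, atol=1e-12)

    def test_matches_power_series_oracle(self, rng):
        X = rng.standard_normal((5, 4))
        SG = build_sample_graph(X, k=2)
        H = rng.standard_normal((5, 4))
        got = random_propagation(H, SG, 2)
        S = np.asarray(SG.similarity.todense())
        d = 1.0 / np.sqrt(S.sum(axis=1))
        Ahat = d[:, None] * S * d[None, :]
        oracle = (H + Ahat @ H + Ahat @ (Ahat @ H)) / 3
        np.testing.assert_allclose(got, oracle, atol=1e-10)

    def test_size_mismatch_errors(self, rng):
        with pytest.raises(ValueError):
            random_propagation(rng.standard_normal((4, 2)), np.eye(5), 1)


class TestMLPForward:
    def _params(self, rng, g=5, hidden=(4,), C=2):
        return init_params(g, hidden, C, rng)

    def test_rows_sum_to_one(self, rng):
        params = self._params(rng)
        Z = mlp_forward(rng.standard_normal((7, 5)), params)
        np.testing.assert_allclose(Z.sum(axis=1), np.ones(7), atol=1e-9)
        assert np.all((Z >= 0) & (Z <= 1))

    def test_zero_final_layer_gives_uniform(self, rng):
        params = self._params(rng)
        params.mlp_weights[-1][:] = 0.0
        params.mlp_biases[-1][:] = 0.0
        Z = mlp_forward(rng.standard_normal((3, 5)), params)
        np.testing.assert_allclose(Z, np.full((3, 2), 0.5), atol=1e-12)

    def test_two_output_classes_by_default(self, rng):
        Z = mlp_forward(rng.standard_normal((3, 5)), self._params(rng))
        assert Z.shape == (3, 2)


class TestForwardPasses:
    def _setup(self, rng, n=10, g=6):
        X = rng.standard_normal((n, g))
        A = np.eye(g)
        SG = build_sample_graph(X, k=3)
        cfg = HiRANDConfig(S=4, delta=0.5, K=1, seed=7, hidden=(8,))
        params = init_params(g, cfg.hidden, 2, rng)
        return X, A, SG, params, cfg

    def test_S_views_and_determinism(self, rng):
        X, A, SG, params, cfg = self._setup(rng)
        ps1 = forward_train(X, A, SG, params, cfg)
        ps2 = forward_train(X, A, SG, params, cfg)
        assert len(ps1.per_view) == 4
        for a, b in zip(ps1.per_view, ps2.per_view):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(ps1.sharpened, ps2.sharpened)

    def test_delta_zero_views_identical(self, rng):
        X, A, SG, params, cfg = self._setup(rng)
        cfg = HiRANDConfig(S=3, delta=0.0, K=1, seed=7, hidden=(8,))
        ps = forward_train(X, A, SG, params, cfg)
        for Z in ps.per_view[1:]:
            np.testing.assert_array_equal(Z, ps.per_view[0])
        np.testing.assert_allclose(ps.center, ps.per_view[0])

    def test_inference_deterministic_and_row_stochastic(self, rng):
        X, A, SG, params, cfg = self._setup(rng)
        Z1 = forward_inference(X, A, SG, params, cfg)
        Z2 = forward_inference(X, A, SG, params, cfg)
        np.testing.assert_array_equal(Z1, Z2)
        np.testing.assert_allclose(Z1.sum(axis=1), 1.0, atol=1e-9)

    def test_inference_equals_training_view_when_delta_zero(self, rng):
        X, A, SG, params, _ = self._setup(rng)
        cfg = HiRANDConfig(S=1, delta=0.0, K=1, seed=7, hidden=(8,))
        ps = forward_train(X, A, SG, params, cfg)
        Z = forward_inference(X, A, SG, params, cfg)
        np.testing.assert_allclose(ps.per_view[0], Z, atol=1e-12)

    def test_permutation_equivariance(self, rng):
        X, A, SG, params, cfg = self._setup(rng)
        perm = rng.permutation(X.shape[0])
        SGp = build_sample_graph(X[perm], k=3)
        Z = forward_inference(X, A, SG, params, cfg)
        Zp = forward_inference(X[perm], A, SGp, params, cfg)
        np.testing.assert_allclose(Zp, Z[perm], atol=1e-9)


class TestHiRANDClassifier:
    def _semi_labels(self, y, per_class, rng):
        semi = np.full(y.size, -1)
        for cls in (0, 1):
            pos = rng.choice(np.flatnonzero(y == cls), per_class, replace=False)
            semi[pos] = cls
        return semi

    def test_sklearn_params_clone(self):
        from sklearn.base import clone
        clf = HiRANDClassifier(S=2, delta=0.3)
        clone_ = clone(clf)
        assert clone_.get_params()["S"] == 2
        assert clone_.get_params()["delta"] == 0.3

    def test_fit_predict_api(self, tiny_dataset, rng):
        ds = tiny_dataset
        semi = self._semi_labels(ds.y, 4, rng)
        clf = HiRANDClassifier(gene_adjacency=ds.feature_graph, epochs=60,
                               k_neighbors=5, random_state=0)
        clf.fit(ds.X.values, semi)
        proba = clf.predict_proba(ds.X.values)
        assert proba.shape == (24, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        pred = clf.predict(ds.X.values)
        assert set(np.unique(pred)) <= {0, 1}
        assert clf.feature_importances_.sum() == pytest.approx(1.0)

    def test_predict_on_new_samples(self, tiny_dataset, rng):
        ds = tiny_dataset
        train, test = np.arange(18), np.arange(18, 24)
        semi = self._semi_labels(ds.y[train], 3, rng)
        clf = HiRANDClassifier(gene_adjacency=ds.feature_graph, epochs=60,
                               k_neighbors=5, random_state=0)
        clf.fit(ds.X.values[train], semi)
        proba = clf.predict_proba(ds.X.values[test])
        assert proba.shape == (6, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_label_validation(self, tiny_dataset):
        ds = tiny_dataset
        clf = HiRANDClassifier(epochs=5, k_neighbors=5)
        with pytest.raises(ValueError, match="both classes"):
            clf.fit(ds.X.values, np.where(ds.y == 1, 1, -1))
        with pytest.raises(ValueError, match="at least one labeled"):
            clf.fit(ds.X.values, np.full(24, -1))


class TestCheckpoint:
    def test_save_load_roundtrip(self, tiny_dataset, rng, tmp_path):
        ds = tiny_dataset
        semi = np.full(24, -1)
        semi[np.flatnonzero(ds.y == 0)[:3]] = 0
        semi[np.flatnonzero(ds.y == 1)[:3]] = 1
        clf = HiRANDClassifier(gene_adjacency=ds.feature_graph, epochs=40,
                               k_neighbors=5, random_state=1)
        clf.fit(ds.X.values, semi)
        path = tmp_path / "model.npz"
        clf.save(path)
        loaded = HiRANDClassifier.load(path)
        np.testing.assert_allclose(loaded.transduction_proba_,
                                   clf.transduction_proba_, atol=1e-12)
        np.testing.assert_array_equal(loaded.predict(ds.X.values),
                                      clf.predict(ds.X.values))
        np.testing.assert_allclose(loaded.feature_importances_,
                                   clf.feature_importances_)
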