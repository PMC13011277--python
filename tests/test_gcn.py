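"""Graph-convolution forward pass, gradients, training and evaluation."""

import numpy as np
import pytest

from optisyn.gcn import (FEATURE_COLUMNS, GCNSynergyClassifier,
                         build_feature_matrix, edge_probability, evaluate_model,
                         gcn_forward, normalize_adjacency, sample_negatives,
                         train_test_split_edges)

import pandas as pd


class TestAdjacency:
    def test_empty_edges_is_identity(self):
        np.testing.assert_allclose(normalize_adjacency([], 3), np.eye(3))

    def test_single_edge_two_nodes_all_half(self):
        # A+I = all-ones, D = diag(2, 2) -> every entry 1/2
        np.testing.assert_allclose(normalize_adjacency([(0, 1)], 2),
                                   np.full((2, 2), 0.5))

    def test_spectral_radius_at_most_one(self):
        # the defining property of symmetric normalisation: eigenvalues of
        # D^{-1/2}(A+I)D^{-1/2} lie in (-1, 1], so propagation cannot blow up
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(3, 12))
            edges = [(int(a), int(b)) for a, b in
                     rng.integers(0, n, size=(n, 2)) if a != b]
            adj = normalize_adjacency(edges, n)
            np.testing.assert_allclose(adj, adj.T, atol=1e-15)
            eig = np.linalg.eigvalsh(adj)
            assert eig.max() <= 1 + 1e-12
            assert eig.min() > -1
            assert (adj.sum(axis=1) > 0).all()

    def test_out_of_range_edge_rejected(self):
        with pytest.raises(ValueError):
            normalize_adjacency([(0, 5)], 3)


class TestForward:
    def test_single_node_identity_weights_reproduces_input(self):
        X = np.array([[2.0, 3.0]])
        H = gcn_forward(X, np.array([[1.0]]), [np.eye(2), np.eye(2)])
        np.testing.assert_allclose(H, X)  # ReLU of positives

    def test_zero_weights_zero_embeddings(self):
        X = np.random.default_rng(0).normal(size=(4, 3))
        adj = normalize_adjacency([(0, 1), (2, 3)], 4)
        H = gcn_forward(X, adj, [np.zeros((3, 2)), np.zeros((2, 2))])
        np.testing.assert_allclose(H, 0.0)

    @pytest.mark.parametrize("activation", ["linear", "relu"])
    def test_three_node_path_matches_hand_oracle(self, activation):
        X = np.array([[1.0, -1.0], [0.5, 2.0], [-2.0, 1.0]])
        adj = normalize_adjacency([(0, 1), (1, 2)], 3)
        G1 = np.array([[0.3, -0.7], [1.2, 0.4]])
        G2 = np.array([[1.0, 0.5], [-0.5, 0.25]])
        H = gcn_forward(X, adj, [G1, G2], activation=activation)
        # independent hand computation of Eq.-style propagation
        def act(z):
            return z if activation == "linear" else np.maximum(z, 0)
        expected = act(adj @ act(adj @ X @ G1) @ G2)
        np.testing.assert_allclose(H, expected, atol=1e-12)

    def test_dropout_only_in_training_mode(self):
        X = np.ones((5, 4))
        adj = np.eye(5)
        W = [np.eye(4), np.eye(4)]
        rng = np.random.default_rng(0)
        H_train = gcn_forward(X, adj, W, dropout=0.5, rng=rng)
        H_eval = gcn_forward(X, adj, W)
        assert not np.allclose(H_train, H_eval)
        np.testing.assert_allclose(gcn_forward(X, adj, W), H_eval)


class TestDecoder:
    def test_zero_score_gives_half_probability_label_zero(self):
        s, p, lab = edge_probability(np.zeros(3), np.ones(3), np.ones(3))
        assert (s, p, lab) == (0.0, 0.5, 0)

    def test_closed_form_sigmoid(self):
        s, p, lab = edge_probability(np.ones(2), np.ones(2), np.ones(2))
        assert s == 2.0
        assert p == pytest.approx(1 / (1 + np.exp(-2)))
        assert lab == 1

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            hi, hj, w = rng.normal(size=(3, 8))
            s1, _, _ = edge_probability(hi, hj, w)
            s2, _, _ = edge_probability(hj, hi, w)
            assert s1 == pytest.approx(s2, abs=1e-15)

    def test_dim_mismatch(self):
        with pytest.raises(ValueError):
            edge_probability(np.zeros(2), np.zeros(3), np.zeros(3))


class TestNegativeSampling:
    def test_disjoint_from_positives(self):
        pos = [(0, 1), (2, 3)]
        negs = sample_negatives(range(5), pos, ratio=1.0, seed=0)
        assert len(negs) == 2
        assert all(frozenset((i, j)) not in {frozenset(p) for p in pos}
                   for i, j, _ in negs)

    def test_overdraw_rejected(self):
        # 5 nodes -> 10 pairs, 2 positives -> 8 in the complement
        with pytest.raises(ValueError):
            sample_negatives(range(5), [(0, 1), (2, 3)], ratio=4.5, seed=0)

    def test_seed_reproducible(self):
        pos = [(0, 1)]
        a = sample_negatives(range(6), pos, ratio=3.0, seed=7)
        b = sample_negatives(range(6), pos, ratio=3.0, seed=7)
        assert a == b


class TestFeatureMatrix:
    def _raw(self, n=8, seed=0):
        rng = np.random.default_rng(seed)
        d = {"herb": [f"h{i}" for i in range(n)]}
        for c in FEATURE_COLUMNS:
            d[c] = rng.normal(size=n)
        return pd.DataFrame(d)

    def test_standardised_columns(self):
        fm = build_feature_matrix(self._raw())
        np.testing.assert_allclose(fm.X.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(fm.X.std(axis=0), 1.0, atol=1e-12)
        assert fm.X.shape == (8, 12)

    def test_constant_column_becomes_zero(self):
        raw = self._raw()
        raw["ec"] = 5.0
        fm = build_feature_matrix(raw)
        np.testing.assert_allclose(fm.X[:, fm.columns.index("ec")], 0.0)

    def test_row_order_invariance(self):
        raw = self._raw()
        fm1 = build_feature_matrix(raw)
        fm2 = build_feature_matrix(raw.sample(frac=1.0, random_state=1))
        np.testing.assert_allclose(fm1.X, fm2.X, atol=1e-12)
        assert fm1.herbs == fm2.herbs

    def test_majority_missing_herb_rejected(self):
        raw = self._raw()
        raw.loc[0, FEATURE_COLUMNS[:8]] = np.nan
        with pytest.raises(ValueError, match="h0"):
            build_feature_matrix(raw)

    def test_median_imputation(self):
        raw = self._raw()
        raw.loc[0, "mscore"] = np.nan
        fm = build_feature_matrix(raw)
        assert np.isfinite(fm.X).all()


def _toy_edge_problem(seed=0, n=16):
    """Node features directly encode a propensity; pairs of high-propensity
    nodes are positive."""
    rng = np.random.default_rng(seed)
    X = np.zeros((n, 12))
    prop = rng.normal(size=n)
    X[:, 0] = prop
    X[:, 1:] = rng.normal(size=(n, 11)) * 0.1
    pairs = np.array([(i, j) for i in range(n) for j in range(i + 1, n)])
    score = prop[pairs[:, 0]] + prop[pairs[:, 1]]
    y = (score > np.quantile(score, 0.7)).astype(int)
    return X, pairs, y


class TestTraining:
    def test_gradients_match_finite_differences(self):
        """Hand-derived backward pass against numerical differentiation."""
        rng = np.random.default_rng(0)
        n, F, h = 5, 3, 4
        X = rng.normal(size=(n, F))
        pairs = np.array([[0, 1], [1, 2], [3, 4], [0, 4]])
        y = np.array([1.0, 0.0, 1.0, 0.0])
        adj = normalize_adjacency([(0, 1), (3, 4)], n)
        weights = [rng.normal(size=(F, h)) * 0.5, rng.normal(size=(h, h)) * 0.5]
        w = rng.normal(size=h)

        def loss_fn(weights, w):
            H = gcn_forward(X, adj, weights, "relu")
            s = (H[pairs[:, 0]] * H[pairs[:, 1]] * w[None, :]).sum(axis=1)
            p = np.clip(1 / (1 + np.exp(-s)), 1e-12, 1 - 1e-12)
            return -(y * np.log(p) + (1 - y) * np.log(1 - p)).mean()

        # analytic gradients via one no-dropout training step's backward pass
        H, cache = gcn_forward(X, adj, weights, "relu", return_cache=True)
        s = (H[pairs[:, 0]] * H[pairs[:, 1]] * w[None, :]).sum(axis=1)
        p = 1 / (1 + np.exp(-s))
        g_score = (p - y) / len(y)
        dH = np.zeros_like(H)
        hi, hj = H[pairs[:, 0]], H[pairs[:, 1]]
        np.add.at(dH, pairs[:, 0], g_score[:, None] * w[None, :] * hj)
        np.add.at(dH, pairs[:, 1], g_score[:, None] * w[None, :] * hi)
        dw = (g_score[:, None] * hi * hj).sum(axis=0)
        grads = [None, None]
        cur = dH
        for l in (1, 0):
            dZ = cur * (cache["pre"][l] > 0)
            grads[l] = cache["inputs"][l].T @ dZ
            if l > 0:
                cur = adj.T @ (dZ @ weights[l].T)

        eps = 1e-6
        for l in range(2):
            for idx in [(0, 0), (1, 2), (2, 1)]:
                Wp = [g.copy() for g in weights]
                Wm = [g.copy() for g in weights]
                Wp[l][idx] += eps
                Wm[l][idx] -= eps
                num = (loss_fn(Wp, w) - loss_fn(Wm, w)) / (2 * eps)
                assert grads[l][idx] == pytest.approx(num, abs=1e-5)
        for d in range(len(w)):
            wp, wm = w.copy(), w.copy()
            wp[d] += eps
            wm[d] -= eps
            num = (loss_fn(weights, wp) - loss_fn(weights, wm)) / (2 * eps)
            assert dw[d] == pytest.approx(num, abs=1e-5)

    def test_zero_learning_rate_leaves_parameters_at_init(self):
        X, pairs, y = _toy_edge_problem()
        a = GCNSynergyClassifier(node_features=X, learning_rate=0.0,
                                 max_epochs=5, dropout=0.0, val_fraction=0.0,
                                 random_state=1).fit(pairs, y)
        b = GCNSynergyClassifier(node_features=X, learning_rate=1e-3,
                                 max_epochs=5, dropout=0.0, val_fraction=0.0,
                                 random_state=1).fit(pairs, y)
        init = GCNSynergyClassifier(node_features=X, learning_rate=0.0,
                                    max_epochs=1, dropout=0.0, val_fraction=0.0,
                                    random_state=1).fit(pairs, y)
        np.testing.assert_allclose(a.w_, init.w_, atol=1e-15)
        for ga, gi in zip(a.weights_, init.weights_):
            np.testing.assert_allclose(ga, gi, atol=1e-15)
        assert any(not np.allclose(gb, gi) for gb, gi in zip(b.weights_, init.weights_))

    def test_training_loss_decreases_on_learnable_problem(self):
        X, pairs, y = _toy_edge_problem(seed=1)
        model = GCNSynergyClassifier(node_features=X, learning_rate=1e-2,
                                     dropout=0.0, max_epochs=60,
                                     val_fraction=0.0, random_state=0).fit(pairs, y)
        assert model.loss_history_[-1] < model.loss_history_[0]

    def test_single_class_rejected(self):
        X, pairs, _ = _toy_edge_problem()
        with pytest.raises(ValueError):
            GCNSynergyClassifier(node_features=X).fit(pairs[:4], np.ones(4))

    def test_message_passing_graph_uses_training_positives_only(self):
        X, pairs, y = _toy_edge_problem(seed=2)
        tr_p, tr_y, te_p, te_y = train_test_split_edges(pairs, y, seed=0)
        model = GCNSynergyClassifier(node_features=X, val_fraction=0.0,
                                     random_state=0).fit(tr_p, tr_y)
        graph_edges = {frozenset(e) for e in model.train_positive_edges_}
        train_pos = {frozenset(p) for p, lab in zip(map(tuple, tr_p), tr_y) if lab == 1}
        test_edges = {frozenset(p) for p in map(tuple, te_p)}
        assert graph_edges == train_pos
        assert not (graph_edges & test_edges)
        # and Â has no entry for any test-only pair
        for i, j in te_p:
            if frozenset((int(i), int(j))) not in train_pos:
                assert model.adjacency_[i, j] == 0.0

    def test_seeded_fit_is_deterministic(self):
        X, pairs, y = _toy_edge_problem(seed=3)
        a = GCNSynergyClassifier(node_features=X, random_state=5).fit(pairs, y)
        b = GCNSynergyClassifier(node_features=X, random_state=5).fit(pairs, y)
        np.testing.assert_array_equal(a.predict_proba(pairs), b.predict_proba(pairs))

    def test_checkpoint_written(self, tmp_path):
        X, pairs, y = _toy_edge_problem(seed=4)
        model = GCNSynergyClassifier(node_features=X, random_state=0).fit(pairs, y)
        p = tmp_path / "ckpt.json"
        model.save(p)
        import json

        payload = json.loads(p.read_text())
        assert payload["hyperparameters"]["hidden_dim"] == 32
        assert len(payload["decoder_w"]) == 32


class TestEvaluation:
    class _Fixed:
        def __init__(self, probs):
            self.probs = np.asarray(probs, dtype=float)

        def predict_proba(self, pairs):
            return np.column_stack([1 - self.probs, self.probs])

    def test_perfect_predictor(self):
        m = evaluate_model(self._Fixed([0.99, 0.99, 0.01, 0.01]),
                           np.zeros((4, 2)), [1, 1, 0, 0])
        assert m["accuracy"] == 1.0
        assert m["auc"] == 1.0
        assert m["rmse"] == pytest.approx(0.01)

    def test_constant_half_predictor(self):
        m = evaluate_model(self._Fixed([0.5] * 4), np.zeros((4, 2)), [1, 0, 1, 0])
        assert m["auc"] == 0.5
        assert m["rmse"] == 0.5
        assert m["mae"] == 0.5

    def test_confusion_worked_example(self):
        # TP=3, FP=1, FN=1, TN=5
        y = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        probs = [0.9, 0.8, 0.7, 0.2, 0.6, 0.1, 0.1, 0.2, 0.3, 0.4]
        m = evaluate_model(self._Fixed(probs), np.zeros((10, 2)), y)
        assert m["precision"] == pytest.approx(0.75)
        assert m["recall"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(0.75)
        assert m["accuracy"] == pytest.approx(0.8)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate_model(self._Fixed([0.5]), np.zeros((1, 2)), [1])
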