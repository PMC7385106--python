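import numpy as np
import pytest

from conftest import random_network
from tns import (
    PAD,
    RegressorSpec,
    ScoreVector,
    TemporalNetwork,
    TrainingConfig,
    build_regressor,
    feature_matrix,
    feature_tensor,
    fit_mli,
    generate_temporal_ba,
    load_model,
    rank,
    save_model,
    score_nodes,
    select_neighborhood,
    train,
)
from tns._cnn import mse_loss
from tns.mli import MLIRegressor


class TestSelectNeighborhood:
    def test_toy_chain_priority_order(self, toy4):
        # 1-hop {0, 2} sorted by temporal degree (2 beats 0), then 2-hop {3}
        assert select_neighborhood(toy4, 1, 4) == [1, 2, 0, 3]

    def test_isolated_node_padded(self):
        net = TemporalNetwork(4, [{(1, 2)}])
        assert select_neighborhood(net, 0, 4) == [0, PAD, PAD, PAD]

    def test_full_clique_degree_sorted(self):
        net = TemporalNetwork(
            4, [{(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)}, {(1, 2)}]
        )
        # temporal degrees: 0 -> 3, 1 -> 4, 2 -> 4, 3 -> 3; anchor 0 first
        assert select_neighborhood(net, 0, 4) == [0, 1, 2, 3]

    def test_truncation_at_d(self, toy4):
        assert select_neighborhood(toy4, 1, 2) == [1, 2]

    def test_index_breaks_degree_ties(self):
        net = TemporalNetwork(3, [{(0, 1), (0, 2)}])
        assert select_neighborhood(net, 0, 3) == [0, 1, 2]


class TestFeatureMatrix:
    def test_toy_chain_worked_example(self, toy4):
        # slots [1, 2]; forward-decay weights w = (1, 0.5, 0.25)
        mat = feature_matrix(toy4, 1, 2, alpha=0.5)
        np.testing.assert_allclose(mat, [[1.5, 0.5], [0.5, 0.75]])

    def test_isolated_node_zero_matrix(self):
        net = TemporalNetwork(3, [{(1, 2)}])
        assert np.all(feature_matrix(net, 0, 4, 0.2) == 0)

    def test_alpha_one_degenerates_to_aggregation(self, toy4):
        mat = feature_matrix(toy4, 1, 4, alpha=1.0)
        # slots [1,2,0,3]; diagonal = temporal degrees, off-diagonal =
        # co-occurrence counts
        assert mat[0, 0] == 2 and mat[1, 1] == 2 and mat[2, 2] == 1
        assert mat[0, 1] == 1 and mat[0, 2] == 1 and mat[1, 3] == 1
        assert mat[2, 3] == 0

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            net = random_network(rng)
            v = int(rng.integers(net.n_nodes))
            mat = feature_matrix(net, v, 8, 0.2)
            np.testing.assert_array_equal(mat, mat.T)
            assert np.all(mat >= 0)

    def test_relabeling_equivariance(self):
        net = TemporalNetwork(4, [{(0, 1), (2, 3)}, {(1, 2)}])
        perm = [2, 0, 3, 1]
        relabeled = net.relabel(perm)
        for v in range(4):
            np.testing.assert_allclose(
                feature_matrix(net, v, 4, 0.3),
                feature_matrix(relabeled, perm[v], 4, 0.3),
            )

    def test_tensor_max_normalized(self, toy4):
        feats = feature_tensor(toy4, 4, 0.5)
        assert feats.shape == (4, 1, 4, 4)
        assert feats.max() == pytest.approx(1.0)

    def test_invalid_alpha_rejected(self, toy4):
        with pytest.raises(ValueError):
            feature_matrix(toy4, 0, 4, alpha=0.0)


class TestRegressorArchitecture:
    def test_fc_input_dimension_formula(self):
        assert RegressorSpec(8).fc_in == 128
        assert RegressorSpec(4).fc_in == 32
        assert RegressorSpec(12).fc_in == 288

    def test_d_not_divisible_by_four_rejected(self):
        for bad in (6, 7, 9, 2):
            with pytest.raises(ValueError):
                RegressorSpec(bad)

    def test_batch_shape_contract(self):
        model = build_regressor(RegressorSpec(8), seed=0)
        out = model.predict(np.zeros((5, 1, 8, 8)))
        assert out.shape == (5,)

    def test_same_seed_identical_initial_weights(self):
        a = build_regressor(RegressorSpec(8), seed=3)
        b = build_regressor(RegressorSpec(8), seed=3)
        for wa, wb in zip(a.net.get_weights(), b.net.get_weights()):
            np.testing.assert_array_equal(wa, wb)

    def test_feature_shape_mismatch_rejected(self):
        model = build_regressor(RegressorSpec(8), seed=0)
        with pytest.raises(ValueError):
            model.predict(np.zeros((2, 1, 4, 4)))

    def test_gradients_match_finite_differences(self):
        # spot-check the hand-written backward pass on a tiny D=4 model
        rng = np.random.default_rng(7)
        model = build_regressor(RegressorSpec(4), seed=7)
        x = rng.random((3, 1, 4, 4))
        y = rng.random(3)

        def loss_value():
            return mse_loss(model.net.forward(x).ravel(), y)[0]

        base, dpred = mse_loss(model.net.forward(x).ravel(), y)
        model.net.backward(dpred[:, None])
        grads = [g.copy() for g in model.net.grads]
        params = model.net.params
        eps = 1e-6
        check = [(0, (0, 0, 1, 1)), (1, (2,)), (4, (10, 0)), (5, (0,))]
        for pi, idx in check:
            params[pi][idx] += eps
            up = loss_value()
            params[pi][idx] -= 2 * eps
            down = loss_value()
            params[pi][idx] += eps
            numeric = (up - down) / (2 * eps)
            assert grads[pi][idx] == pytest.approx(numeric, rel=1e-4, abs=1e-8)


class TestTraining:
    def _toy_data(self, seed=0, n=24):
        net = generate_temporal_ba(n, 1, 4, seed=seed)
        feats = feature_tensor(net, 4, 0.2)
        rng = np.random.default_rng(seed)
        labels = feats[:, 0].sum(axis=(1, 2)) + 0.01 * rng.random(n)
        return feats, labels

    def test_constant_labels_converge_to_constant(self):
        feats, _ = self._toy_data()
        labels = np.full(len(feats), 0.37)
        model = build_regressor(RegressorSpec(4), seed=1)
        cfg = TrainingConfig(epochs=50, batch_size=8, seed=1)
        model, _ = train(model, feats, labels, cfg)
        assert np.allclose(model.predict(feats), 0.37, atol=1e-2)

    def test_loss_decreases(self):
        feats, labels = self._toy_data(seed=2)
        model = build_regressor(RegressorSpec(4), seed=2)
        _, history = train(
            model, feats, labels, TrainingConfig(epochs=30, batch_size=8, seed=2)
        )
        assert history[-1] < history[0]

    def test_identical_seeds_identical_histories(self):
        feats, labels = self._toy_data(seed=3)
        histories = []
        for _ in range(2):
            model = build_regressor(RegressorSpec(4), seed=3)
            _, h = train(
                model, feats, labels, TrainingConfig(epochs=10, batch_size=8, seed=3)
            )
            histories.append(h)
        assert histories[0] == histories[1]

    def test_label_count_mismatch_rejected(self):
        feats, labels = self._toy_data()
        model = build_regressor(RegressorSpec(4), seed=0)
        with pytest.raises(ValueError):
            train(model, feats, labels[:-1], TrainingConfig(epochs=1))


class TestScoringAndRanking:
    def test_rank_tie_break_by_index(self):
        # descending score; the tied 0.9s keep ascending node order
        scores = ScoreVector("x", np.array([0.3, 0.9, 0.9, 0.1]))
        assert rank(scores).tolist() == [1, 2, 0, 3]

    def test_d_mismatch_rejected(self, toy4):
        model = build_regressor(RegressorSpec(8), seed=0)
        with pytest.raises(ValueError):
            score_nodes(model, toy4, d=4)

    def test_identical_features_identical_scores(self):
        net = TemporalNetwork(3, [set()])  # all-isolated: all-zero features
        model = build_regressor(RegressorSpec(4), seed=5)
        scores = score_nodes(model, net, d=4).values
        assert scores[0] == scores[1] == scores[2]

    def test_scoring_respects_relabeling(self):
        # distinct temporal degrees (4, 7, 5, 3, 1) so neighbourhood slot
        # order cannot depend on node indices
        net = TemporalNetwork(
            5,
            [
                {(0, 1), (1, 2), (2, 3), (3, 4)},
                {(0, 1), (1, 2), (2, 3)},
                {(0, 1), (1, 2)},
                {(0, 1)},
            ],
        )
        perm = [3, 0, 4, 1, 2]
        model = build_regressor(RegressorSpec(4), seed=8)
        base = score_nodes(model, net, d=4).values
        moved = score_nodes(model, net.relabel(perm), d=4).values
        for v in range(5):
            assert moved[perm[v]] == pytest.approx(base[v])


class TestPersistence:
    def test_round_trip_preserves_predictions(self, tmp_path):
        net = generate_temporal_ba(20, 1, 3, seed=9)
        cfg = TrainingConfig(epochs=5, label_runs=5, seed=9)
        model, _ = fit_mli(net, cfg, RegressorSpec(4))
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        feats = feature_tensor(net, 4, 0.2)
        np.testing.assert_array_equal(loaded.predict(feats), model.predict(feats))
        assert loaded.spec == model.spec
        assert loaded.config == cfg

    def test_loaded_model_refuses_wrong_d(self, tmp_path, toy4):
        model = build_regressor(RegressorSpec(4), seed=0)
        model.config = None
        save_model(model, tmp_path / "m.npz")
        loaded = load_model(tmp_path / "m.npz")
        with pytest.raises(ValueError):
            score_nodes(loaded, toy4, d=8)
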