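"""Network tests: initializer, loss, gradients, autoencoder, transfer,
classifier training and inference."""

import numpy as np
import pytest
from sklearn.decomposition import PCA

from druglike.errors import DataError
from druglike.network import (
    Autoencoder,
    DrugLikenessClassifier,
    NetworkParams,
    TrainingConfig,
    forward,
    init_truncated_normal,
    predict,
    train_autoencoder,
    transfer_weights,
    weighted_bce,
)

from conftest import numerical_gradients


class TestTruncatedNormal:
    def test_truncation_bound(self):
        w = init_truncated_normal((200, 50), stddev=0.05, seed=0)
        assert np.abs(w).max() <= 2 * 0.05

    def test_monte_carlo_mean(self):
        w = init_truncated_normal((100_000,), stddev=0.05, seed=1)
        # sample mean within 3 standard errors of 0 (SE bounded by sigma/sqrt n)
        assert abs(w.mean()) < 3 * 0.05 / np.sqrt(100_000)

    def test_seeded_determinism(self):
        a = init_truncated_normal((20, 20), 0.1, seed=3)
        b = init_truncated_normal((20, 20), 0.1, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_bad_stddev(self):
        with pytest.raises(DataError):
            init_truncated_normal((2, 2), stddev=0.0)


class TestWeightedBce:
    def test_half_weight_factors_standard_ce(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            y = rng.integers(0, 2, 64)
            a = rng.uniform(0.01, 0.99, 64)
            standard = -float(np.sum(y * np.log(a) + (1 - y) * np.log(1 - a)))
            assert weighted_bce(y, a, 0.5) == pytest.approx(0.5 * standard, rel=1e-10)

    def test_hand_computed_case(self):
        # -(0.7 ln 0.9 + 0.3 ln 0.8) ~= 0.140695
        got = weighted_bce([1, 0], [0.9, 0.2], 0.7)
        assert got == pytest.approx(0.14069542635474122, abs=1e-6)

    def test_perfect_predictions_vanish(self):
        assert weighted_bce([1, 0], [1.0, 0.0], 0.6) < 1e-5

    def test_mean_variant(self):
        y, a = [1, 0, 1, 0], [0.8, 0.3, 0.6, 0.2]
        assert weighted_bce(y, a, 0.7, "mean") == pytest.approx(
            weighted_bce(y, a, 0.7, "sum") / 4)

    @pytest.mark.parametrize("w", [0.0, 1.0, -0.2, 1.5])
    def test_weight_out_of_range(self, w):
        with pytest.raises(DataError):
            weighted_bce([1], [0.5], w)


class TestGradients:
    @pytest.mark.parametrize("hidden", [(8,), (6, 4)])
    def test_analytic_matches_finite_differences(self, hidden):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(4, 5))
        y = np.array([1, 0, 1, 0])
        clf = DrugLikenessClassifier(hidden_dims=hidden, l2=1e-3, pos_weight=0.7,
                                     dropout=0.0, seed=2)
        params = clf._init_params(5)
        loss, gW, gb = clf.loss_and_grads(X, y, params, reduction="sum")

        def loss_fn():
            return clf.loss_and_grads(X, y, params, reduction="sum")[0]

        num_W = numerical_gradients(loss_fn, params.weights)
        num_b = numerical_gradients(loss_fn, params.biases)
        for ana, num in zip(gW + gb, num_W + num_b):
            np.testing.assert_allclose(ana, num, rtol=1e-5, atol=1e-7)


def low_rank_data(n=200, p=12, r=3, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, r)) @ rng.normal(size=(r, p))
    if noise:
        X = X + rng.normal(scale=noise, size=X.shape)
    return X - X.mean(axis=0)


class TestAutoencoder:
    def test_identity_capacity(self):
        # hidden dim = input dim with linear activation: identity map exists
        X = low_rank_data(n=100, p=5, r=5, seed=1)
        ae = Autoencoder(hidden_dims=(5,), activation="linear", l2=0.0, dropout=0.0,
                         learning_rate=2e-2, max_epochs=800, batch_size=32, seed=0).fit(X)
        assert ae.reconstruction_mse(X) < 1e-3

    def test_descent_sanity(self):
        X = low_rank_data(seed=2)
        ae = Autoencoder(hidden_dims=(4,), max_epochs=20, seed=0).fit(X)
        trace = ae.trace_[0]
        assert trace[-1] <= trace[0]

    def test_linear_ae_near_pca_optimum(self):
        """A rank-r linear autoencoder should approach the rank-r PCA
        reconstruction error (optimal linear compression)."""
        X = low_rank_data(n=150, p=10, r=2, seed=3, noise=0.3)
        ae = Autoencoder(hidden_dims=(2,), activation="linear", l2=0.0, dropout=0.0,
                         learning_rate=1e-2, max_epochs=400, batch_size=64, seed=0).fit(X)
        pca = PCA(n_components=2).fit(X)
        pca_mse = float(((pca.inverse_transform(pca.transform(X)) - X) ** 2).mean())
        total_var = float(X.var())
        assert ae.reconstruction_mse(X) <= pca_mse + 0.10 * total_var

    def test_stacked_layerwise_shapes(self):
        X = low_rank_data(n=80, p=10, r=4, seed=4)
        ae = Autoencoder(hidden_dims=(6, 3), max_epochs=5, seed=0).fit(X)
        assert [W.shape for W in ae.encoder_weights_] == [(10, 6), (6, 3)]
        assert ae.transform(X).shape == (80, 3)
        assert ae.reconstruct(X).shape == X.shape
        assert len(ae.trace_) == 2

    def test_non_finite_input_fatal(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(DataError):
            Autoencoder(max_epochs=1).fit(X)


class TestTransfer:
    def cfg(self, hidden=(6,)):
        return TrainingConfig(hidden_dims=hidden, ae_epochs=2, max_epochs=2)

    def test_encoder_copied_bit_exact(self):
        X = low_rank_data(n=60, p=8, r=3, seed=5)
        cfg = self.cfg()
        ae_params, _ = train_autoencoder(X, cfg)
        clf_params = transfer_weights(ae_params, cfg)
        np.testing.assert_array_equal(clf_params.weights[0], ae_params.weights[0])
        np.testing.assert_array_equal(clf_params.biases[0], ae_params.biases[0])

    def test_output_layer_shape_and_activation(self):
        X = low_rank_data(n=60, p=8, r=3, seed=5)
        cfg = self.cfg()
        ae_params, _ = train_autoencoder(X, cfg)
        clf_params = transfer_weights(ae_params, cfg)
        assert clf_params.weights[-1].shape == (6, 1)
        assert clf_params.activations[-1] == "sigmoid"
        assert clf_params.role == "classifier"

    def test_seed_isolation(self):
        X = low_rank_data(n=60, p=8, r=3, seed=5)
        cfg = self.cfg()
        ae_params, _ = train_autoencoder(X, cfg)
        a = transfer_weights(ae_params, cfg, seed=1)
        b = transfer_weights(ae_params, cfg, seed=2)
        np.testing.assert_array_equal(a.weights[0], b.weights[0])
        assert not np.array_equal(a.weights[-1], b.weights[-1])

    def test_architecture_mismatch_fatal(self):
        X = low_rank_data(n=60, p=8, r=3, seed=5)
        ae_params, _ = train_autoencoder(X, self.cfg())
        with pytest.raises(DataError, match="mismatch"):
            transfer_weights(ae_params, self.cfg(hidden=(4,)))


class TestClassifier:
    def test_linearly_separable_toy(self):
        rng = np.random.default_rng(9)
        X = np.vstack([rng.normal(2, 0.3, (40, 2)), rng.normal(-2, 0.3, (40, 2))])
        y = np.array([1] * 40 + [0] * 40)
        clf = DrugLikenessClassifier(hidden_dims=(8,), max_epochs=200,
                                     early_stop_patience=200, batch_size=16,
                                     dropout=0.0, seed=0)
        clf.fit(X, y, eval_set=(X, y))
        assert max(clf.trace_["eval_acc"]) == 1.0

    def test_higher_pos_weight_raises_sensitivity(self):
        """On an imbalanced overlapping task, w=0.9 should give median SE at
        least as high as w=0.5 (same seeds)."""
        se = {0.5: [], 0.9: []}
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            X = np.vstack([rng.normal(0.8, 1, (25, 4)), rng.normal(-0.8, 1, (250, 4))])
            y = np.array([1] * 25 + [0] * 250)
            Xt = np.vstack([rng.normal(0.8, 1, (50, 4)), rng.normal(-0.8, 1, (200, 4))])
            yt = np.array([1] * 50 + [0] * 200)
            for w in (0.5, 0.9):
                clf = DrugLikenessClassifier(hidden_dims=(8,), max_epochs=40,
                                             early_stop_patience=40, pos_weight=w,
                                             dropout=0.0, seed=seed)
                clf.fit(X, y)
                tp = int(((clf.predict(Xt) == 1) & (yt == 1)).sum())
                se[w].append(tp / 50)
        assert np.median(se[0.9]) >= np.median(se[0.5])

    def test_zero_weights_predict_half(self):
        params = NetworkParams(
            weights=[np.zeros((3, 4)), np.zeros((4, 1))],
            biases=[np.zeros(4), np.zeros(1)],
            activations=["relu", "sigmoid"],
            role="classifier",
        )
        probs = predict(params, np.random.default_rng(0).normal(size=(6, 3)))
        np.testing.assert_array_equal(probs, np.full(6, 0.5))

    def test_prediction_permutation_equivariant(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(30, 4))
        clf = DrugLikenessClassifier(hidden_dims=(5,), max_epochs=3, seed=0)
        clf.fit(X, rng.integers(0, 2, 30))
        perm = rng.permutation(30)
        p_all = clf.predict_proba(X)[:, 1]
        p_perm = clf.predict_proba(X[perm])[:, 1]
        np.testing.assert_array_equal(p_all[perm], p_perm)

    def test_inference_deterministic_despite_dropout(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(40, 4))
        clf = DrugLikenessClassifier(hidden_dims=(6,), dropout=0.5, max_epochs=3, seed=0)
        clf.fit(X, rng.integers(0, 2, 40))
        a = clf.predict_proba(X)
        b = clf.predict_proba(X)
        np.testing.assert_array_equal(a, b)

    def test_serialization_round_trip(self, tmp_path):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(30, 4))
        clf = DrugLikenessClassifier(hidden_dims=(5,), max_epochs=3, seed=0)
        clf.fit(X, rng.integers(0, 2, 30))
        clf.params_.save(tmp_path / "model")
        loaded = NetworkParams.load(tmp_path / "model")
        for a, b in zip(clf.params_.weights, loaded.weights):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(predict(loaded, X), clf.predict_proba(X)[:, 1])

    def test_dim_mismatch_fatal(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(20, 4))
        clf = DrugLikenessClassifier(hidden_dims=(5,), max_epochs=2, seed=0)
        clf.fit(X, rng.integers(0, 2, 20))
        with pytest.raises(DataError):
            clf.predict(rng.normal(size=(5, 3)))

    def test_sklearn_params_round_trip(self):
        clf = DrugLikenessClassifier(hidden_dims=(7,), pos_weight=0.6)
        params = clf.get_params()
        assert params["pos_weight"] == 0.6
        clone = DrugLikenessClassifier(**params)
        assert clone.get_params() == params
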