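"""RBM and deep-network checks: enumeration oracles for the Boltzmann
conditionals and likelihood gradient, finite-difference backprop checks,
seed determinism, and the semi-supervision benefit."""

import itertools

import numpy as np
import pytest

from tweetmine import dbn
from tweetmine.dbn import (
    DBNModel,
    FinetuneConfig,
    PretrainConfig,
    RBMParams,
    cd_update,
    finetune,
    hidden_probs,
    init_random_model,
    load_model,
    predict_scores,
    pretrain,
    save_model,
    visible_probs,
)


def _small_rbm(nv=4, nh=3, seed=0, scale=0.7):
    rng = np.random.default_rng(seed)
    return RBMParams(
        W=rng.normal(0, scale, size=(nv, nh)),
        vbias=rng.normal(0, scale, size=nv),
        hbias=rng.normal(0, scale, size=nh),
    )


def _energy(rbm, v, h):
    return -(v @ rbm.vbias + h @ rbm.hbias + v @ rbm.W @ h)


def _enumerate_states(nv, nh):
    for v in itertools.product([0.0, 1.0], repeat=nv):
        for h in itertools.product([0.0, 1.0], repeat=nh):
            yield np.array(v), np.array(h)


def _exact_loglik(rbm, V):
    """Mean log p(v) over rows of V by full-state enumeration."""
    nv, nh = rbm.W.shape
    Z = sum(np.exp(-_energy(rbm, v, h)) for v, h in _enumerate_states(nv, nh))
    ll = 0.0
    for v in V:
        pv = sum(
            np.exp(-_energy(rbm, v, np.array(h)))
            for h in itertools.product([0.0, 1.0], repeat=nh)
        )
        ll += np.log(pv / Z)
    return ll / len(V)


class TestRBMConditionals:
    def test_zero_parameters_give_half(self):
        rbm = RBMParams(np.zeros((4, 3)), np.zeros(4), np.zeros(3))
        np.testing.assert_allclose(hidden_probs(rbm, np.ones(4)), 0.5)

    def test_zero_visible_gives_sigmoid_of_bias(self):
        rbm = _small_rbm()
        expected = 1 / (1 + np.exp(-rbm.hbias))
        np.testing.assert_allclose(hidden_probs(rbm, np.zeros(4))[0], expected)

    def test_matches_enumerated_boltzmann_conditional(self):
        """p(h_j=1|v) from the sigmoid formula equals the conditional of the
        enumerated joint Boltzmann distribution (7-unit RBM)."""
        rbm = _small_rbm(nv=4, nh=3, seed=5)
        nh = 3
        for v in itertools.product([0.0, 1.0], repeat=4):
            v = np.array(v)
            weights = {
                h: np.exp(-_energy(rbm, v, np.array(h)))
                for h in itertools.product([0.0, 1.0], repeat=nh)
            }
            total = sum(weights.values())
            for j in range(nh):
                marginal = sum(w for h, w in weights.items() if h[j] == 1.0) / total
                assert hidden_probs(rbm, v)[0, j] == pytest.approx(marginal)

    def test_shape_mismatch_rejected(self):
        rbm = _small_rbm()
        with pytest.raises(ValueError, match="dimension"):
            hidden_probs(rbm, np.zeros(5))
        with pytest.raises(ValueError, match="dimension"):
            visible_probs(rbm, np.zeros(5))


class TestCDUpdate:
    def test_zero_learning_rate_is_identity(self, rng):
        rbm = _small_rbm(seed=1)
        W0 = rbm.W.copy()
        cfg = PretrainConfig(learning_rate=0.0)
        cd_update(rbm, rng.integers(0, 2, size=(6, 4)).astype(float), cfg, rng)
        np.testing.assert_array_equal(rbm.W, W0)

    def test_fixed_point_update_vanishes(self, rng):
        # saturated visible biases reconstruct the all-ones batch exactly, so
        # positive and negative associations cancel
        rbm = RBMParams(np.zeros((4, 3)), np.full(4, 50.0), np.zeros(3))
        batch = np.ones((8, 4))
        cfg = PretrainConfig(learning_rate=0.1)
        cd_update(rbm, batch, cfg, rng)
        np.testing.assert_allclose(rbm.W, 0.0, atol=1e-12)
        np.testing.assert_allclose(rbm.hbias, 0.0, atol=1e-12)

    def test_empty_batch_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            cd_update(_small_rbm(), np.zeros((0, 4)), PretrainConfig(), rng)

    def test_expected_gradient_matches_enumeration_and_fd(self):
        """The CD target direction (data associations minus exact model
        associations) equals the enumerated log-likelihood gradient, itself
        verified against central finite differences."""
        rbm = _small_rbm(nv=3, nh=2, seed=7)
        rng = np.random.default_rng(3)
        V = rng.integers(0, 2, size=(5, 3)).astype(float)

        # analytic gradient: E_data[v h^T] - E_model[v h^T]
        H_data = hidden_probs(rbm, V)
        pos_W = V.T @ H_data / len(V)
        pos_v = V.mean(axis=0)
        pos_h = H_data.mean(axis=0)
        states = list(_enumerate_states(3, 2))
        weights = np.array([np.exp(-_energy(rbm, v, h)) for v, h in states])
        weights /= weights.sum()
        neg_W = sum(w * np.outer(v, h) for w, (v, h) in zip(weights, states))
        neg_v = sum(w * v for w, (v, h) in zip(weights, states))
        neg_h = sum(w * h for w, (v, h) in zip(weights, states))

        eps = 1e-5
        for arr, grad in ((rbm.W, pos_W - neg_W), (rbm.vbias, pos_v - neg_v),
                          (rbm.hbias, pos_h - neg_h)):
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + eps
                up = _exact_loglik(rbm, V)
                arr[idx] = orig - eps
                down = _exact_loglik(rbm, V)
                arr[idx] = orig
                fd = (up - down) / (2 * eps)
                assert fd == pytest.approx(grad[idx], rel=1e-4, abs=1e-7)


class TestPretrain:
    def test_seed_determinism(self, small_feature_matrix):
        X, _, cats = small_feature_matrix
        cfg = PretrainConfig(epochs_per_layer=1, seed=11)
        sizes = (X.shape[1], 16, 12, 8, len(cats))
        m1 = pretrain(X, sizes, cfg, cats)
        m2 = pretrain(X, sizes, cfg, cats)
        for a, b in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(a, b)

    def test_zero_epochs_leaves_log_empty(self, small_feature_matrix):
        X, _, cats = small_feature_matrix
        cfg = PretrainConfig(epochs_per_layer=0, seed=1)
        m = pretrain(X, (X.shape[1], 8, 6, 4, len(cats)), cfg, cats)
        assert all(len(r) == 0 for r in m.pretrain_log["reconstruction_error"])

    def test_reconstruction_error_decreases(self, small_feature_matrix):
        X, _, cats = small_feature_matrix
        cfg = PretrainConfig(epochs_per_layer=5, seed=2)
        m = pretrain(X, (X.shape[1], 32, 16, 8, len(cats)), cfg, cats)
        layer1 = m.pretrain_log["reconstruction_error"][0]
        assert layer1[-1] < layer1[0]

    def test_too_few_layers_rejected(self, small_feature_matrix):
        X, _, cats = small_feature_matrix
        with pytest.raises(ValueError, match="layer"):
            pretrain(X, (X.shape[1], len(cats)), PretrainConfig(), cats)


class TestFinetune:
    def test_zero_learning_rate_is_identity(self, rng):
        m = init_random_model((4, 3, 2), ("a", "b"), seed=3)
        W0 = [w.copy() for w in m.weights]
        X = rng.integers(0, 2, size=(10, 4)).astype(float)
        y = rng.integers(0, 2, size=10)
        finetune(m, X, y, FinetuneConfig(learning_rate=0.0, epochs=3, dropout_rate=0.0))
        for a, b in zip(m.weights, W0):
            np.testing.assert_array_equal(a, b)

    def test_gradient_matches_finite_differences(self):
        """Analytic backprop gradient vs central differences, dropout off."""
        rng = np.random.default_rng(8)
        m = init_random_model((5, 4, 3), ("a", "b", "c"), seed=8, weight_sd=0.5)
        X = rng.integers(0, 2, size=(7, 5)).astype(float)
        y = rng.integers(0, 3, size=7)

        def loss(model):
            scores = model.forward(X)
            return -np.log(scores[np.arange(len(y)), y]).mean()

        # extract analytic gradients: one lr=1 step on a copy
        probe = m.copy()
        cfg = FinetuneConfig(learning_rate=1.0, epochs=1, batch_size=7, dropout_rate=0.0)
        finetune(probe, X, y, cfg)
        eps = 1e-6
        for l in range(len(m.weights)):
            analytic = m.weights[l] - probe.weights[l]
            it = np.nditer(m.weights[l], flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = m.weights[l][idx]
                m.weights[l][idx] = orig + eps
                up = loss(m)
                m.weights[l][idx] = orig - eps
                down = loss(m)
                m.weights[l][idx] = orig
                fd = (up - down) / (2 * eps)
                assert fd == pytest.approx(analytic[idx], rel=1e-5, abs=1e-9)

    def test_separable_two_class_convergence(self):
        rng = np.random.default_rng(4)
        n = 60
        y = rng.integers(0, 2, size=n)
        X = np.zeros((n, 6))
        X[np.arange(n), y * 3] = 1  # disjoint active features per class
        X[:, 2] = rng.integers(0, 2, size=n)
        m = init_random_model((6, 8, 6, 2), ("a", "b"), seed=4)
        # tiny network: a larger step size escapes the small-weight plateau
        finetune(m, X, y, FinetuneConfig(epochs=200, seed=4, learning_rate=0.5))
        acc = (np.argmax(predict_scores(m, X), axis=1) == y).mean()
        assert acc >= 0.95

    def test_label_outside_scheme_rejected(self):
        m = init_random_model((4, 3, 2), ("a", "b"), seed=1)
        with pytest.raises(ValueError, match="label"):
            finetune(m, np.zeros((2, 4)), [0, 5], FinetuneConfig(epochs=1))

    def test_full_replay_determinism(self, small_feature_matrix):
        X, y, cats = small_feature_matrix
        def run():
            m = pretrain(X, (X.shape[1], 12, 10, 8, len(cats)),
                         PretrainConfig(epochs_per_layer=2, seed=6), cats)
            return finetune(m, X, y, FinetuneConfig(epochs=3, seed=7))
        m1, m2 = run(), run()
        for a, b in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(a, b)


class TestPredict:
    def test_rows_sum_to_one(self, rng, small_feature_matrix):
        X, y, cats = small_feature_matrix
        m = init_random_model((X.shape[1], 8, 6, len(cats)), cats, seed=2)
        scores = predict_scores(m, X)
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-9)
        assert ((scores > 0) & (scores < 1)).all()

    def test_zero_network_gives_uniform(self):
        cats = tuple(f"c{i}" for i in range(9))
        m = DBNModel(
            (5, 4, 9),
            [np.zeros((5, 4)), np.zeros((4, 9))],
            [np.zeros(4), np.zeros(9)],
            cats,
        )
        scores = predict_scores(m, np.ones((3, 5)))
        np.testing.assert_allclose(scores, 1 / 9)

    def test_hand_built_network(self):
        W1 = np.array([[0.2, -0.3], [0.4, 0.1]])
        b1 = np.array([0.1, -0.2])
        W2 = np.array([[1.0, -1.0], [0.5, 0.5]])
        b2 = np.array([0.0, 0.1])
        m = DBNModel((2, 2, 2), [W1, W2], [b1, b2], ("a", "b"))
        x = np.array([[1.0, 0.0]])
        h = 1 / (1 + np.exp(-(x @ W1 + b1)))
        logits = h @ W2 + b2
        expected = np.exp(logits) / np.exp(logits).sum()
        np.testing.assert_allclose(m.forward(x), expected, atol=1e-12)

    def test_prediction_is_dropout_free(self, small_feature_matrix):
        X, y, cats = small_feature_matrix
        m = init_random_model((X.shape[1], 8, len(cats)), cats, seed=9)
        np.testing.assert_array_equal(predict_scores(m, X), predict_scores(m, X))

    def test_shape_mismatch(self):
        m = init_random_model((4, 3, 2), ("a", "b"), seed=0)
        with pytest.raises(ValueError, match="columns"):
            predict_scores(m, np.zeros((2, 5)))


class TestSaveLoad:
    def test_round_trip_identical(self, tmp_path, small_feature_matrix):
        X, _, cats = small_feature_matrix
        m = init_random_model((X.shape[1], 7, len(cats)), cats, seed=5)
        p = tmp_path / "model.bin"
        save_model(m, p)
        back = load_model(p)
        assert back.categories == m.categories
        np.testing.assert_array_equal(predict_scores(back, X), predict_scores(m, X))

    def test_truncated_file_rejected(self, tmp_path):
        m = init_random_model((4, 3, 2), ("a", "b"), seed=1)
        p = tmp_path / "model.bin"
        save_model(m, p)
        p.write_bytes(p.read_bytes()[:-16])
        with pytest.raises(ValueError, match="truncated"):
            load_model(p)

    def test_wrong_format_rejected(self, tmp_path):
        p = tmp_path / "junk.bin"
        p.write_bytes(b"\x00\x01binary junk\n more")
        with pytest.raises(ValueError):
            load_model(p)


class TestSemiSupervision:
    def test_pretraining_helps_in_small_label_regime(self, medium_features):
        """Mean 5-fold CV accuracy with RBM pretraining >= without, averaged
        over 3 seeds, with 200 labels and a 10,000-vector unlabeled pool."""
        from tweetmine.evaluation import cross_validate, stratified_folds

        X_all, y_all, cats, U = medium_features
        accs = {"pre": [], "rand": []}
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            idx = rng.choice(len(y_all), size=200, replace=False)
            X, y = X_all[idx], y_all[idx]
            labels = [cats[i] for i in y]
            folds = stratified_folds(labels, k=5, seed=seed)
            pre_cfg = PretrainConfig(epochs_per_layer=3, seed=seed)
            fin_cfg = FinetuneConfig(epochs=10, seed=seed)
            hidden = (48, 48, 24)
            sizes = (X.shape[1], *hidden, len(cats))
            stack = pretrain(U, sizes, pre_cfg, cats)
            for key, init in (("pre", stack), ("rand", None)):
                factory = lambda: dbn.DBNClassifier(  # noqa: B023,E731
                    cats, hidden, pre_cfg, fin_cfg, initial_model=init
                )
                rep = cross_validate(X, labels, factory, folds, cats)
                accs[key].append(rep.accuracy)
        assert np.mean(accs["pre"]) >= np.mean(accs["rand"])
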