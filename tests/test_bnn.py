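"""Variational network: initialisation, forward/backward, KL, training."""

import numpy as np
import pytest

from glycofp.bnn import (
    ArchitectureConfig,
    BayesianSpectrumClassifier,
    TrainConfig,
    VariationalFitResults,
    forward_mean,
    forward_sample,
    init_model,
    kl_divergence,
    loss,
    loss_and_grads,
    train,
)

TOY_ARCH = ArchitectureConfig(input_dim=3, hidden=(2,), n_classes=2, dropout_rate=0.0)


def _near_deterministic(model):
    for r in model.rho_W + model.rho_b:
        r.fill(-40.0)
    return model


class TestInit:
    def test_same_seed_bit_identical(self):
        a = init_model(ArchitectureConfig(), seed=7)
        b = init_model(ArchitectureConfig(), seed=7)
        for x, y in zip(a.mu_W + a.mu_b, b.mu_W + b.mu_b):
            np.testing.assert_array_equal(x, y)

    def test_initial_sigma_is_softplus_of_minus_three(self):
        model = init_model(TOY_ARCH, seed=0)
        assert model.sigma_W()[0][0, 0] == pytest.approx(0.04858735157374196, abs=1e-12)

    def test_parameter_count_default_architecture(self):
        model = init_model(ArchitectureConfig(), seed=0)
        # brute-force count over layer shapes
        sizes = (1200, 300, 225, 100, 4)
        expected = sum(a * b + b for a, b in zip(sizes[:-1], sizes[1:]))
        assert model.n_parameters() == expected == 451_029


class TestForward:
    def test_softmax_rows_normalised(self):
        model = init_model(ArchitectureConfig(input_dim=10, hidden=(8, 6, 4)), seed=1)
        X = np.random.default_rng(0).normal(size=(7, 10))
        probs = forward_sample(model, X, np.random.default_rng(2))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(probs > 0) and np.all(probs < 1)

    def test_deterministic_limit_two_passes_identical(self):
        model = _near_deterministic(init_model(TOY_ARCH, seed=1))
        X = np.random.default_rng(0).normal(size=(4, 3))
        a = forward_sample(model, X, np.random.default_rng(1), training=False)
        b = forward_sample(model, X, np.random.default_rng(2), training=False)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_toy_network_matches_hand_computation(self):
        # 1-2-2 net, sigma ~ 0, hand-set means
        arch = ArchitectureConfig(input_dim=1, hidden=(2,), n_classes=2, dropout_rate=0.0)
        model = _near_deterministic(init_model(arch, seed=0))
        model.mu_W[0][:] = [[1.0, -2.0]]
        model.mu_b[0][:] = [0.5, 0.25]
        model.mu_W[1][:] = [[2.0, -1.0], [0.5, 1.5]]
        model.mu_b[1][:] = [-0.1, 0.2]
        x = np.array([[0.7]])
        h = np.maximum(np.array([0.7 * 1.0 + 0.5, 0.7 * -2.0 + 0.25]), 0.0)
        logits = h @ np.array([[2.0, -1.0], [0.5, 1.5]]) + np.array([-0.1, 0.2])
        expected = np.exp(logits) / np.exp(logits).sum()
        np.testing.assert_allclose(forward_mean(model, x)[0], expected, atol=1e-9)

    def test_matches_independent_mlp_oracle(self):
        # deterministic limit vs sklearn's MLP forward pass on the same weights
        from sklearn.neural_network import MLPClassifier

        arch = ArchitectureConfig(input_dim=6, hidden=(5, 4, 3), n_classes=3,
                                  dropout_rate=0.0)
        model = _near_deterministic(init_model(arch, seed=3))
        rng = np.random.default_rng(4)
        for w in model.mu_W:
            w[:] = rng.normal(scale=0.7, size=w.shape)
        for b in model.mu_b:
            b[:] = rng.normal(scale=0.3, size=b.shape)
        clf = MLPClassifier(hidden_layer_sizes=(5, 4, 3), activation="relu", max_iter=1)
        Xd = rng.normal(size=(10, 6))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(Xd, np.arange(10) % 3)
        clf.coefs_ = [w.copy() for w in model.mu_W]
        clf.intercepts_ = [b.copy() for b in model.mu_b]
        clf.out_activation_ = "softmax"
        X = rng.normal(size=(20, 6))
        np.testing.assert_allclose(
            forward_mean(model, X), clf.predict_proba(X), atol=1e-6
        )


class TestKL:
    def _unit_posterior(self, arch=TOY_ARCH):
        model = init_model(arch, seed=0)
        rho_unit = np.log(np.e - 1.0)  # softplus(rho) = 1
        for mu in model.mu_W + model.mu_b:
            mu.fill(0.0)
        for r in model.rho_W + model.rho_b:
            r.fill(rho_unit)
        return model

    def test_posterior_equal_prior_gives_zero(self):
        assert kl_divergence(self._unit_posterior()) == pytest.approx(0.0, abs=1e-9)

    def test_single_parameter_mu_one(self):
        model = self._unit_posterior()
        model.mu_W[0][0, 0] = 1.0
        assert kl_divergence(model) == pytest.approx(0.5, abs=1e-9)

    def test_single_parameter_sigma_half(self):
        model = self._unit_posterior()
        model.rho_W[0][0, 0] = np.log(np.expm1(0.5))  # softplus^-1(0.5)
        expected = np.log(2.0) + 0.125 - 0.5  # = 0.318147...
        assert kl_divergence(model) == pytest.approx(expected, abs=1e-9)

    def test_nonnegative_for_random_posteriors(self):
        rng = np.random.default_rng(0)
        model = init_model(TOY_ARCH, seed=0)
        for mu in model.mu_W + model.mu_b:
            mu[:] = rng.normal(size=mu.shape)
        for r in model.rho_W + model.rho_b:
            r[:] = rng.normal(size=r.shape)
        assert kl_divergence(model) >= 0.0


class TestLossAndGradients:
    def test_uniform_output_cross_entropy_is_ln4(self):
        arch = ArchitectureConfig(input_dim=5, hidden=(4,), n_classes=4, dropout_rate=0.0)
        model = _near_deterministic(init_model(arch, seed=0))
        for mu in model.mu_W + model.mu_b:
            mu.fill(0.0)
        X = np.random.default_rng(0).normal(size=(6, 5))
        y = np.array([0, 1, 2, 3, 0, 1])
        val = loss(model, X, y, np.random.default_rng(0), kl_weight=0.0)
        assert val == pytest.approx(np.log(4.0), abs=1e-9)

    def test_invalid_label_rejected(self):
        model = init_model(TOY_ARCH, seed=0)
        with pytest.raises(ValueError, match="label"):
            loss(model, np.zeros((1, 3)), np.array([5]), np.random.default_rng(0))

    @pytest.mark.parametrize("dropout,kl_weight", [(0.0, 0.3), (0.25, 0.0)])
    def test_gradients_match_finite_differences(self, dropout, kl_weight):
        arch = ArchitectureConfig(input_dim=3, hidden=(2,), n_classes=2,
                                  dropout_rate=dropout)
        model = init_model(arch, seed=5)
        rng0 = np.random.default_rng(6)
        for p in model.mu_W + model.mu_b:
            p[:] = rng0.normal(scale=0.5, size=p.shape)
        for r in model.rho_W + model.rho_b:
            r[:] = rng0.normal(loc=-1.0, scale=0.3, size=r.shape)
        X = rng0.normal(size=(5, 3))
        y = np.array([0, 1, 1, 0, 1])

        def f():
            # fixed rng seed -> identical eps and dropout masks on every call
            return loss(model, X, y, np.random.default_rng(11), mc_samples=2,
                        kl_weight=kl_weight)

        _, _, _, grads = loss_and_grads(
            model, X, y, np.random.default_rng(11), mc_samples=2, kl_weight=kl_weight
        )
        h = 1e-6
        for key, arrays in (("mu_W", model.mu_W), ("rho_W", model.rho_W),
                            ("mu_b", model.mu_b), ("rho_b", model.rho_b)):
            for li, arr in enumerate(arrays):
                flat = arr.ravel()
                for idx in range(flat.size):
                    orig = flat[idx]
                    flat[idx] = orig + h
                    fp = f()
                    flat[idx] = orig - h
                    fm = f()
                    flat[idx] = orig
                    fd = (fp - fm) / (2 * h)
                    an = grads[key][li].ravel()[idx]
                    assert an == pytest.approx(fd, rel=1e-4, abs=1e-7), (key, li, idx)


class TestTraining:
    def _separable_toy(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 10))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        X[y == 1] += 1.5
        return X, y

    def test_separable_toy_reaches_full_training_accuracy(self):
        X, y = self._separable_toy()
        arch = ArchitectureConfig(input_dim=10, hidden=(8, 6, 4), n_classes=2)
        model = init_model(arch, seed=1)
        # negligible KL: at n=20 the posterior regularizer would rightly
        # dominate, but this checks the likelihood optimisation alone
        model, _ = train(
            model, (X, y), None,
            TrainConfig(epochs=200, batch_size=10, seed=1, kl_weight=1e-8),
        )
        assert np.mean(forward_mean(model, X).argmax(axis=1) == y) == 1.0

    def test_same_seed_identical_history(self, small_corpus):
        xt, yt, xv, yv, classes = small_corpus.arrays()
        cfg = TrainConfig(epochs=3, seed=2)
        fit1 = BayesianSpectrumClassifier(xt, yt, xv, yv, classes=classes).fit(cfg)
        fit2 = BayesianSpectrumClassifier(xt, yt, xv, yv, classes=classes).fit(cfg)
        assert fit1.history.equals(fit2.history)
        np.testing.assert_array_equal(fit1.model.mu_W[0], fit2.model.mu_W[0])

    def test_loss_decreases_and_sigma_stays_positive(self, small_corpus):
        xt, yt, xv, yv, classes = small_corpus.arrays()
        fit = BayesianSpectrumClassifier(xt, yt, xv, yv, classes=classes).fit(
            TrainConfig(epochs=5, seed=3)
        )
        losses = fit.history["loss"].to_numpy()
        assert np.all(np.diff(losses) < 0)
        for s in fit.model.sigma_W() + fit.model.sigma_b():
            assert np.all(s > 0)

    def test_empty_training_set_rejected(self):
        model = init_model(TOY_ARCH, seed=0)
        with pytest.raises(ValueError, match="empty"):
            train(model, (np.zeros((0, 3)), np.zeros(0, dtype=int)), None, TrainConfig())

    def test_summary_and_checkpoint_roundtrip(self, small_corpus, tmp_path):
        xt, yt, xv, yv, classes = small_corpus.arrays()
        fit = BayesianSpectrumClassifier(xt, yt, xv, yv, classes=classes).fit(
            TrainConfig(epochs=2, seed=4)
        )
        text = fit.summary()
        assert "451029" in text.replace(",", "") or "parameters" in text
        fit.save(tmp_path / "ckpt")
        back = VariationalFitResults.load(tmp_path / "ckpt")
        np.testing.assert_allclose(back.predict_proba(xv[:5]), fit.predict_proba(xv[:5]))
        assert back.classes == classes
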