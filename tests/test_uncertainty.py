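"""MC predictive moments: oracle equivalence, the closed-form limit, OOD score."""

import numpy as np
import pytest

from uqgan import (ClassFrequencySpec, DropoutConfig, GeneratorSpec,
                   NetworkParameters, build_generator, mc_predict, ood_score,
                   predictive_mean, predictive_uncertainty,
                   sample_configuration)


def _random_prob_maps(rng, n, c, h, w):
    raw = rng.random((n, c, h, w)) + 1e-3
    return list(raw / raw.sum(axis=1, keepdims=True))


def _uncertainty_oracle(samples, tau):
    """Independent brute-force evaluation: loop over pixels and members."""
    n = len(samples)
    c, h, w = samples[0].shape
    u = np.zeros((h, w, c, c))
    for i in range(h):
        for j in range(w):
            vecs = [s[:, i, j] for s in samples]
            mean = sum(vecs) / n
            second = sum(np.outer(v, v) for v in vecs) / n
            u[i, j] = np.diag(1.0 / np.asarray(tau)) + second \
                - np.outer(mean, mean)
    return u


class TestPredictiveMean:
    def test_symmetric_pair(self):
        a = np.array([[[1.0]], [[0.0]]])
        b = np.array([[[0.0]], [[1.0]]])
        np.testing.assert_array_equal(predictive_mean([a, b]),
                                      np.array([[[0.5]], [[0.5]]]))

    def test_idempotent_on_identical_samples(self, rng):
        s = _random_prob_maps(rng, 1, 3, 4, 4)[0]
        np.testing.assert_allclose(predictive_mean([s, s, s]), s, atol=1e-15)

    def test_matches_elementwise_oracle(self, rng):
        samples = _random_prob_maps(rng, 7, 3, 5, 6)
        oracle = sum(samples) / len(samples)
        np.testing.assert_allclose(predictive_mean(samples), oracle, atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            predictive_mean([])


class TestPredictiveUncertainty:
    def test_worked_two_sample_example(self):
        """Two opposite hard predictions, tau=(1/2,1/2):
        u = [[2.25, -0.25], [-0.25, 2.25]]."""
        a = np.array([[[1.0]], [[0.0]]])
        b = np.array([[[0.0]], [[1.0]]])
        u = predictive_uncertainty([a, b], ClassFrequencySpec((0.5, 0.5)))
        np.testing.assert_allclose(
            u[0, 0], np.array([[2.25, -0.25], [-0.25, 2.25]]), atol=1e-15)

    def test_zero_spread_gives_inverse_frequency_diagonal(self, rng):
        s = _random_prob_maps(rng, 1, 2, 3, 3)[0]
        u = predictive_uncertainty([s, s], ClassFrequencySpec((0.5, 0.5)))
        np.testing.assert_allclose(u, np.broadcast_to(2.0 * np.eye(2),
                                                      (3, 3, 2, 2)), atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        samples = _random_prob_maps(rng, 5, 3, 4, 4)
        tau = (0.7, 0.2, 0.1)
        u = predictive_uncertainty(samples, ClassFrequencySpec(tau))
        np.testing.assert_allclose(u, _uncertainty_oracle(samples, tau),
                                   atol=1e-12)

    def test_symmetry(self, rng):
        samples = _random_prob_maps(rng, 6, 4, 3, 3)
        u = predictive_uncertainty(samples,
                                   ClassFrequencySpec((0.4, 0.3, 0.2, 0.1)))
        np.testing.assert_allclose(u, np.swapaxes(u, -1, -2), atol=1e-12)

    def test_diagonal_only_agrees_with_full(self, rng):
        samples = _random_prob_maps(rng, 5, 3, 4, 4)
        freq = ClassFrequencySpec((0.5, 0.3, 0.2))
        full = predictive_uncertainty(samples, freq)
        diag = predictive_uncertainty(samples, freq, diagonal_only=True)
        np.testing.assert_allclose(diag, np.diagonal(full, axis1=-2, axis2=-1),
                                   atol=1e-12)

    def test_zero_frequency_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ClassFrequencySpec((1.0, 0.0))

    def test_scalar_tau_mode(self, rng):
        samples = _random_prob_maps(rng, 3, 2, 2, 2)
        freq = ClassFrequencySpec((0.8, 0.2), tau_mode="scalar")
        u = predictive_uncertainty(samples, freq)
        uv = predictive_uncertainty(samples, ClassFrequencySpec((0.8, 0.2)))
        # same covariance part, different constant offset
        np.testing.assert_allclose(u - freq.inverse_offset(),
                                   uv - np.diag([1 / 0.8, 1 / 0.2]), atol=1e-12)
        np.testing.assert_allclose(freq.inverse_offset(), 2.0 * np.eye(2))


class TestMCPredict:
    def test_single_member_sigma_zero_is_plain_forward(self, rng):
        G = build_generator(GeneratorSpec(stacks=1, base_channels=4,
                                          noise_dim=4, n_down=2), seed=1)
        x = rng.random((1, 32, 32))
        z = rng.normal(size=4)
        params = G.get_parameters()
        maps = mc_predict(G, params, x, z, DropoutConfig(sigma=0.0, n_samples=1))
        np.testing.assert_array_equal(maps[0], G.forward_zx(z, x))

    def test_deterministic_and_restores_base_params(self, rng):
        G = build_generator(GeneratorSpec(stacks=1, base_channels=4,
                                          noise_dim=4, n_down=2), seed=2)
        x = rng.random((1, 32, 32))
        z = rng.normal(size=4)
        params = G.get_parameters()
        cfg = DropoutConfig(sigma=0.2, n_samples=5, seed=4)
        maps1 = mc_predict(G, params, x, z, cfg)
        assert G.get_parameters() == params
        maps2 = mc_predict(G, params, x, z, cfg)
        assert all(np.array_equal(a, b) for a, b in zip(maps1, maps2))
        for m in maps1:
            np.testing.assert_allclose(m.sum(axis=0), 1.0, atol=1e-5)


class TestOodScore:
    def test_zero_variance_scores_zero(self):
        freq = ClassFrequencySpec((0.5, 0.5))
        u = np.broadcast_to(freq.inverse_offset(), (4, 4, 2, 2))
        assert ood_score(u, freq) == 0.0

    def test_constant_variance_field_scores_that_variance(self):
        freq = ClassFrequencySpec((0.5, 0.5))
        v = 0.123
        u = np.broadcast_to(freq.inverse_offset()
                            + np.diag([v / 2, v / 2]), (3, 3, 2, 2))
        assert ood_score(u, freq, reduction="mean") == pytest.approx(v)
        assert ood_score(u, freq, reduction="max") == pytest.approx(v)
        assert ood_score(u, freq, reduction="quantile", q=0.5) \
            == pytest.approx(v)

    def test_quantile_requires_q(self):
        freq = ClassFrequencySpec((0.5, 0.5))
        u = np.broadcast_to(freq.inverse_offset(), (2, 2, 2, 2))
        with pytest.raises(ValueError, match="requires q"):
            ood_score(u, freq, reduction="quantile")


class TestAnalyticLimit:
    def test_linear_toy_variance_matches_closed_form(self):
        """y = theta*delta*x with delta ~ N(1, sigma): Var(y) = sigma^2
        theta^2 x^2; MC at N=10^5 agrees within 5%."""
        theta, x, sigma = 2.0, 3.0, 0.5
        p = NetworkParameters([np.full(1, theta)])
        cfg = DropoutConfig(sigma=sigma, n_samples=100_000, seed=17)
        ys = np.array([sample_configuration(p, cfg, i).theta[0][0] * x
                       for i in range(cfg.n_samples)])
        closed = sigma ** 2 * theta ** 2 * x ** 2
        assert abs(ys.var() - closed) / closed < 0.05

    def test_variance_monotone_in_sigma(self, rng):
        """Total predictive variance is non-decreasing in sigma on a frozen
        net and fixed batch."""
        G = build_generator(GeneratorSpec(stacks=1, base_channels=4,
                                          noise_dim=4, n_down=2), seed=6)
        params = G.get_parameters()
        x = rng.random((1, 32, 32))
        z = rng.normal(size=4)
        freq = ClassFrequencySpec((0.9, 0.09, 0.01))
        scores = []
        for sigma in (0.0, 0.1, 0.3):
            cfg = DropoutConfig(sigma=sigma, n_samples=8, seed=21)
            maps = mc_predict(G, params, x, z, cfg)
            u = predictive_uncertainty(maps, freq)
            scores.append(ood_score(u, freq))
        assert scores[0] <= scores[1] <= scores[2]
        assert scores[0] == 0.0
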