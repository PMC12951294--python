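"""Mean-reverting SDE: schedule construction, marginals, score, sampling."""

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from patdiff.errors import ConfigurationError, PatdiffError
from patdiff.sde import (
    DiffusionSchedule,
    build_schedule,
    marginal_params,
    reverse_sample,
    sample_forward,
    score_from_noise,
    training_loss,
)


def constant_rate_schedule(theta0: float, lam: float, T: int = 200) -> DiffusionSchedule:
    """Unscaled constant-rate schedule for continuous-time cross-checks."""
    times = np.linspace(0.0, 1.0, T + 1)
    theta = np.full(T + 1, theta0)
    return DiffusionSchedule(
        T, lam, times, theta,
        np.sqrt(2.0 * lam**2 * theta),
        cumulative_trapezoid(theta, times, initial=0.0),
    )


class TestBuildSchedule:
    @pytest.mark.parametrize("kind", ["cosine", "constant"])
    def test_volatility_rate_identity(self, kind):
        s = build_schedule(200, 50.0, kind)
        mask = s.theta > 0
        np.testing.assert_allclose((s.sigma**2 / np.where(mask, s.theta, 1.0))[mask],
                                   2 * 50.0**2, rtol=1e-12)

    @pytest.mark.parametrize("kind", ["cosine", "constant"])
    def test_terminal_convergence(self, kind):
        s = build_schedule(200, 50.0, kind)
        assert np.exp(-2 * s.theta_bar[-1]) <= 1e-4 + 1e-12
        assert np.all(np.diff(s.theta_bar) >= 0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            build_schedule(T=1)
        with pytest.raises(ConfigurationError):
            build_schedule(lam=0.0)
        with pytest.raises(ConfigurationError):
            build_schedule(kind="banana")


class TestMarginalParams:
    def test_t_zero_returns_clean_image(self):
        s = build_schedule()
        x0, mu = np.full((4, 4), 7.0), np.zeros((4, 4))
        m, v = marginal_params(x0, mu, 0, s)
        np.testing.assert_array_equal(m, x0)
        assert v == 0.0

    def test_terminal_limit_approaches_mu_and_lambda_sq(self):
        s = build_schedule(lam=50.0)
        x0, mu = np.zeros((2, 2)), np.full((2, 2), 100.0)
        m, v = marginal_params(x0, mu, s.T, s)
        np.testing.assert_allclose(m, 100.0, atol=100.0 * np.sqrt(1e-4) + 1e-9)
        assert v == pytest.approx(50.0**2, rel=2e-4)

    def test_out_of_range_state_rejected(self):
        s = build_schedule()
        with pytest.raises(PatdiffError):
            marginal_params(np.zeros(2), np.zeros(2), s.T + 1, s)

    def test_matches_euler_maruyama_monte_carlo(self):
        """Closed form vs a brute-force SDE integration, theta=1, t=0.5."""
        lam, theta0 = 50.0, 1.0
        s = constant_rate_schedule(theta0, lam, T=200)
        x0, mu = 0.0, 100.0
        m, v = marginal_params(np.array(x0), np.array(mu), 100, s)  # t = 0.5
        assert m == pytest.approx(100.0 * (1 - np.exp(-0.5)), rel=1e-12)
        assert v == pytest.approx(2500.0 * (1 - np.exp(-1.0)), rel=1e-12)

        n_paths, n_steps, t_end = 100_000, 500, 0.5
        dt = t_end / n_steps
        rng = np.random.default_rng(12345)
        x = np.full(n_paths, x0)
        sigma = np.sqrt(2 * lam**2 * theta0)
        for _ in range(n_steps):
            x += theta0 * (mu - x) * dt + sigma * np.sqrt(dt) * rng.standard_normal(n_paths)
        se_mean = x.std() / np.sqrt(n_paths)
        assert abs(x.mean() - m) < 3 * se_mean + 0.05  # + Euler bias allowance
        se_var = x.var() * np.sqrt(2.0 / n_paths)
        assert abs(x.var() - v) < 3 * se_var + 0.01 * v


class TestSampleForward:
    def test_t_zero_is_exact(self):
        s = build_schedule()
        x0 = np.arange(9.0).reshape(3, 3)
        state = sample_forward(x0, np.zeros((3, 3)), 0, s, np.random.default_rng(0))
        np.testing.assert_array_equal(state.x_t, x0)

    def test_fixed_seed_reproducible(self):
        s = build_schedule()
        draws = [sample_forward(np.zeros((4, 4)), np.ones((4, 4)), 70, s,
                                np.random.default_rng(9)) for _ in range(2)]
        np.testing.assert_array_equal(draws[0].x_t, draws[1].x_t)
        np.testing.assert_array_equal(draws[0].eps, draws[1].eps)

    def test_mid_schedule_moments(self):
        s = build_schedule()
        n = 100_000
        x0 = np.full(n, 30.0)
        mu = np.full(n, 130.0)
        t = s.T // 2
        m, v = marginal_params(x0[:1], mu[:1], t, s)
        state = sample_forward(x0, mu, t, s, np.random.default_rng(3))
        se_mean = np.sqrt(v / n)
        assert abs(state.x_t.mean() - m[0]) < 4 * se_mean
        se_var = v * np.sqrt(2.0 / n)
        assert abs(state.x_t.var() - v) < 4 * se_var

    def test_marginal_law_across_schedule(self):
        """Empirical mean/variance at ten states match the closed form."""
        s = build_schedule()
        n = 10_000
        x0, mu = np.full(n, 10.0), np.full(n, 90.0)
        rng = np.random.default_rng(17)
        for t in np.linspace(1, s.T, 10, dtype=int):
            m, v = marginal_params(x0[:1], mu[:1], int(t), s)
            state = sample_forward(x0, mu, int(t), s, rng)
            assert abs(state.x_t.mean() - m[0]) < 4 * np.sqrt(v / n) + 1e-9
            assert abs(state.x_t.var() - v) < 4 * v * np.sqrt(2.0 / n) + 1e-9


class TestScore:
    def test_zero_noise_zero_score(self):
        assert np.all(score_from_noise(np.zeros((3, 3)), 4.0) == 0.0)

    def test_negating_noise_negates_score(self):
        eps = np.random.default_rng(0).normal(size=(5, 5))
        np.testing.assert_array_equal(score_from_noise(-eps, 2.0),
                                      -score_from_noise(eps, 2.0))

    def test_zero_variance_rejected(self):
        with pytest.raises(PatdiffError):
            score_from_noise(np.zeros(3), 0.0)

    def test_equals_gaussian_identity_for_generated_states(self):
        s = build_schedule()
        rng = np.random.default_rng(5)
        x0 = rng.uniform(0, 255, (8, 8))
        mu = rng.uniform(0, 255, (8, 8))
        state = sample_forward(x0, mu, 120, s, rng)
        m, v = marginal_params(x0, mu, 120, s)
        np.testing.assert_allclose(score_from_noise(state.eps, v),
                                   -(state.x_t - m) / v, rtol=1e-10, atol=1e-12)


class TestTrainingLoss:
    def _batch(self, rng, n=3, shape=(16, 16)):
        return [(rng.uniform(0, 255, shape), rng.uniform(0, 255, shape))
                for _ in range(n)]

    def test_oracle_network_scores_zero(self):
        s = build_schedule()
        rng = np.random.default_rng(2)
        batch = self._batch(rng)
        truth = {}

        class Oracle:
            def __call__(self, x_t, mu, t):
                x0 = truth["x0"]
                m, v = marginal_params(x0, mu, t, s)
                return (x_t - m) / np.sqrt(v)

        oracle = Oracle()
        for x0, mu in batch:
            truth["x0"] = x0
            loss = training_loss(oracle, [(x0, mu)], s, np.random.default_rng(7))
            assert loss == pytest.approx(0.0, abs=1e-20)

    def test_zero_network_scores_unit_loss(self):
        s = build_schedule()
        batch = self._batch(np.random.default_rng(4), n=8, shape=(32, 32))
        loss = training_loss(lambda x, m, t: np.zeros_like(x), batch, s,
                             np.random.default_rng(11))
        n_pix = 8 * 32 * 32
        assert abs(loss - 1.0) < 4 * np.sqrt(2.0 / n_pix)

    def test_empty_batch_rejected(self):
        with pytest.raises(PatdiffError):
            training_loss(lambda x, m, t: x, [], build_schedule(),
                          np.random.default_rng(0))


class TestReverseSample:
    def test_fixed_seed_is_deterministic(self):
        s = build_schedule(T=50)
        mu = np.full((8, 8), 100.0)
        net = lambda x, m, t: (x - m) / np.sqrt(max(s.variance(t / s.T), 1e-6))
        a = reverse_sample(mu, net, s, np.random.default_rng(1))
        b = reverse_sample(mu, net, s, np.random.default_rng(1))
        np.testing.assert_array_equal(a, b)

    def test_near_deterministic_limit_inverts_the_ode(self):
        """With a vanishing noise level and the analytic score, the reverse
        integration is a deterministic ODE whose solution returns x0."""
        lam = 1e-3
        s = build_schedule(T=200, lam=lam)
        x0 = np.array([200.0])
        mu = np.array([80.0])

        def score(x, t):
            decay = s.mean_decay(t)
            m = mu + (x0 - mu) * decay
            v = s.variance(t)
            return -(x - m) / np.maximum(v, 1e-30)

        out = reverse_sample(mu, None, s, np.random.default_rng(0), steps=20000,
                             score_fn=score, stochastic=False)
        assert abs(out[0] - x0[0]) / x0[0] <= 1e-3

    def test_error_shrinks_as_steps_double(self):
        """Analytic-score restoration improves (in expectation) with step count."""
        s = build_schedule(T=200)
        x0 = np.full(256, 200.0)
        mu = np.full(256, 80.0)

        def score(x, t):
            decay = s.mean_decay(t)
            m = mu + (x0 - mu) * decay
            return -(x - m) / np.maximum(s.variance(t), 1e-12)

        errors = []
        for steps in (25, 50, 100, 200):
            out = reverse_sample(mu, None, s, np.random.default_rng(42),
                                 steps=steps, score_fn=score)
            errors.append(np.abs(out - 200.0).mean())
        assert errors[-1] < errors[0]
        for a, b in zip(errors, errors[1:]):
            assert b <= a * 1.1  # monotone within Monte-Carlo slack

    def test_requires_exactly_one_score_source(self):
        s = build_schedule(T=10)
        with pytest.raises(ConfigurationError):
            reverse_sample(np.zeros(3), None, s, np.random.default_rng(0))
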