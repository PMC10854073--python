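import numpy as np
import pytest
from scipy import integrate
from hypothesis import given, settings
from hypothesis import strategies as st

from rayssf.kernels import (
    cartesian_logpdf,
    fit_gamma_lengths,
    gamma_moment_start,
    jacobian_det,
    plain_diffusion_scale,
    polar_logpdf,
    sample_cartesian,
    sample_gamma_polar,
    sample_polar,
)


class TestPolarLogpdf:
    def test_density_vanishes_at_zero_length(self):
        assert polar_logpdf(0.0, 1.0, 2.0) == -np.inf

    def test_mode_over_length_is_sigma(self):
        sigma2 = 3.7
        sigma = np.sqrt(sigma2)
        l = np.linspace(1e-3, 5 * sigma, 4001)
        dens = polar_logpdf(l, 1.0, sigma2)
        assert abs(l[np.argmax(dens)] - sigma) < 2 * (l[1] - l[0])

    def test_joint_density_integrates_to_one(self):
        """Numeric quadrature oracle: ∫∫ exp(logpdf) dl dθ = 1."""
        sigma2 = 2.5
        val, err = integrate.dblquad(
            lambda l, th: np.exp(polar_logpdf(l, th, sigma2)),
            0.0, 2 * np.pi - 1e-12,          # θ
            0.0, 20 * np.sqrt(sigma2),       # l
            epsabs=1e-10,
        )
        assert abs(val - 1.0) < 1e-6

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            polar_logpdf(-1.0, 0.0, 1.0)

    def test_angle_outside_support_rejected(self):
        with pytest.raises(ValueError):
            polar_logpdf(1.0, 7.0, 1.0)


class TestCartesianLogpdf:
    def test_peak_value_at_origin(self):
        assert cartesian_logpdf((0, 0), (0, 0), 1.0) == pytest.approx(
            np.log(1 / (2 * np.pi))
        )

    def test_rotation_invariance(self, rng):
        sigma2 = 2.0
        r = 1.7
        vals = [
            cartesian_logpdf((r * np.cos(a), r * np.sin(a)), (0, 0), sigma2)
            for a in rng.uniform(0, 2 * np.pi, 20)
        ]
        assert np.ptp(vals) < 1e-12

    def test_change_of_variables_identity(self, rng):
        """polar = cartesian + log l at matched points (Jacobian = l)."""
        for _ in range(100):
            sigma2 = rng.uniform(0.1, 10)
            l = rng.uniform(0.01, 5 * np.sqrt(sigma2))
            th = rng.uniform(0, 2 * np.pi)
            origin = rng.uniform(-5, 5, 2)
            endpoint = origin + [l * np.cos(th), l * np.sin(th)]
            lhs = polar_logpdf(l, th, sigma2)
            rhs = cartesian_logpdf(endpoint, origin, sigma2) + np.log(l)
            assert lhs == pytest.approx(rhs, rel=1e-10)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_variance_rejected(self, bad):
        with pytest.raises(ValueError):
            cartesian_logpdf((0, 0), (0, 0), bad)


class TestJacobian:
    def test_literal_values(self):
        assert jacobian_det(5.0, 0.3) == pytest.approx(5.0, abs=1e-12)
        assert jacobian_det(0.0, 2.1) == 0.0

    def test_equals_length_on_dense_angle_grid(self):
        theta = np.linspace(0, 2 * np.pi, 1000)
        l = np.full_like(theta, 3.25)
        np.testing.assert_allclose(jacobian_det(l, theta), l, rtol=1e-14)

    def test_matches_high_precision_evaluation(self):
        import sympy

        ls, ts = sympy.symbols("l theta", positive=True)
        expr = ls * sympy.cos(ts) ** 2 + ls * sympy.sin(ts) ** 2
        for lv, tv in [(2.0, 0.1), (7.5, 4.4), (0.3, 6.0)]:
            exact = float(expr.subs({ls: lv, ts: tv}).evalf(30))
            assert jacobian_det(lv, tv) == pytest.approx(exact, rel=1e-12)


class TestSamplers:
    def test_polar_reproducible_given_seed(self):
        a = sample_polar((1, 2), 4.0, 10, np.random.default_rng(3))
        b = sample_polar((1, 2), 4.0, 10, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    def test_polar_second_moment_matches_rayleigh(self):
        # E[l²] = 2σ²
        rng = np.random.default_rng(5)
        pts = sample_polar((0, 0), 4.0, 100_000, rng)
        l2 = (pts**2).sum(axis=1)
        assert abs(l2.mean() - 8.0) / 8.0 < 0.02

    def test_cartesian_mean_and_variance(self):
        rng = np.random.default_rng(6)
        sigma2 = 3.0
        M = 100_000
        pts = sample_cartesian((5, -2), sigma2, M, rng)
        bound = 3 * np.sqrt(sigma2 / M)
        assert np.all(np.abs(pts.mean(axis=0) - [5, -2]) < bound)
        assert np.all(np.abs(pts.var(axis=0) - sigma2) / sigma2 < 0.02)

    def test_polar_and_cartesian_agree_distributionally(self):
        from scipy import stats

        rng = np.random.default_rng(7)
        xp = sample_polar((0, 0), 2.0, 20_000, rng)[:, 0]
        xc = sample_cartesian((0, 0), 2.0, 20_000, rng)[:, 0]
        assert stats.ks_2samp(xp, xc).pvalue > 0.01

    def test_gamma_sampler_length_mean(self):
        rng = np.random.default_rng(8)
        pts = sample_gamma_polar((0, 0), 2.0, 0.5, 50_000, rng)
        l = np.hypot(pts[:, 0], pts[:, 1])
        assert abs(l.mean() - 4.0) / 4.0 < 0.02


class TestPlainDiffusion:
    def test_single_step_closed_form(self):
        assert plain_diffusion_scale([2.0], [4.0]) == pytest.approx(0.5)

    def test_regular_dt_reduces_to_rayleigh_mle(self, rng):
        l = rng.rayleigh(1.3, 200)
        assert plain_diffusion_scale(l, np.ones(200)) == pytest.approx(
            np.sum(l**2) / (2 * 200)
        )

    def test_recovers_scale_at_mixed_intervals(self):
        rng = np.random.default_rng(9)
        dt = rng.choice([3.0, 4.0, 8.0], 10_000)
        l = np.sqrt(dt) * rng.rayleigh(1.5, 10_000)
        est = plain_diffusion_scale(l, dt)
        assert abs(est - 2.25) / 2.25 < 0.05

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            plain_diffusion_scale([], [])


class TestGammaFit:
    def test_exponential_data_gives_unit_shape(self):
        rng = np.random.default_rng(10)
        model = fit_gamma_lengths(rng.exponential(1.0, 10_000))
        assert abs(model.shape - 1.0) < 0.05
        assert model.converged

    def test_moment_start_closed_form(self):
        l = np.array([1.0, 2.0, 3.0])
        shape, rate = gamma_moment_start(l)
        v = np.var(l)
        assert shape == pytest.approx(4.0 / v)
        assert rate == pytest.approx(2.0 / v)

    def test_mle_dominates_moment_start(self, rng):
        from rayssf.kernels import _gamma_loglik

        l = rng.gamma(2.5, 1.7, 500)
        model = fit_gamma_lengths(l)
        mom = _gamma_loglik(*gamma_moment_start(l), l)
        assert model.loglik >= mom - 1e-9

    def test_zeros_excluded_and_counted(self, rng):
        l = np.concatenate([rng.gamma(2.0, 1.0, 300), [0.0, 0.0]])
        model = fit_gamma_lengths(l)
        assert model.n_zero_dropped == 2
        assert model.n == 300

    def test_degenerate_equal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal"):
            fit_gamma_lengths(np.full(10, 3.0))
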