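import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from plastinorm import (
    ModelParams,
    PopulationState,
    QuadratureSpec,
    constant_phenotypic_variance,
    env_mean_fitness,
    environment_weights,
    global_mean_fitness,
    individual_fitness,
    optimal_breeding_date,
    phenotypic_variance,
    response_in_environment,
    selection_gradient_intercept,
    selection_gradient_slope,
    selection_gradients,
    total_response,
    solve_equilibrium_numeric,
)
from conftest import random_state, random_valid_params

TINY = 1e-12  # effectively-degenerate variance


class TestOptimumAndFitness:
    @pytest.mark.parametrize(
        "n,A,B,expected", [(0, 0, -1, 0.0), (2, 0, -1, -2.0), (-1, 5, -3, 8.0)]
    )
    def test_optimum_is_linear_in_nutrition(self, n, A, B, expected):
        assert optimal_breeding_date(n, ModelParams(A=A, B=B)) == pytest.approx(expected)

    def test_fitness_on_optimum_no_nutrition_effect(self, ref_params):
        theta = optimal_breeding_date(0.0, ref_params)
        assert individual_fitness(theta, 0.0, 0.0, ref_params) == pytest.approx(1.0)

    def test_fitness_nutrition_term_only(self, ref_params):
        theta = optimal_breeding_date(1.0, ref_params)
        assert individual_fitness(theta, 0.0, 1.0, ref_params) == pytest.approx(np.e)

    def test_fitness_mismatch_penalty(self):
        p = ModelParams(alpha=0.0, omega_y2=20.0)
        theta = optimal_breeding_date(0.0, p)
        assert individual_fitness(theta + 2.0, 0.0, 0.0, p) == pytest.approx(np.exp(-0.1))

    @given(y=st.floats(-50, 50), b=st.floats(-5, 5), n=st.floats(-5, 5))
    @settings(derandomize=True, max_examples=50)
    def test_fitness_strictly_positive(self, y, b, n):
        assert individual_fitness(y, b, n, ModelParams()) > 0


class TestEnvMeanFitness:
    def test_degenerate_population_on_optimum(self):
        # no-cost representation: with a finite cost width the slope mu_b = B
        # itself would be penalized and Wbar < 1
        p = ModelParams(alpha=0.0, omega_b2=1e12,
                        sigma_ai2=TINY, sigma_ei2=0, sigma_ab2=TINY, sigma_eb2=0)
        state = PopulationState(p.A, p.B)
        for n in (-1.3, 0.0, 2.0):
            assert env_mean_fitness(n, state, p) == pytest.approx(1.0, rel=1e-9)

    def test_degenerate_population_alpha_term_only(self):
        p = ModelParams(alpha=1.0, sigma_ai2=TINY, sigma_ei2=0, sigma_ab2=TINY, sigma_eb2=0)
        state = PopulationState(p.A + p.B, 0.0)  # phenotype on optimum at n=1, slope 0
        assert env_mean_fitness(1.0, state, p) == pytest.approx(np.e, rel=1e-9)

    @pytest.mark.parametrize("rho", [0.0, 0.6, -0.8])
    def test_matches_two_dimensional_quadrature(self, rho, rng):
        """Closed-form Gaussian integral vs brute-force 2-D integration."""
        p = random_valid_params(rng, rho=rho)
        state = random_state(rng)
        n = float(rng.normal())
        S = p.phenotypic_cov()
        Si, det = np.linalg.inv(S), np.linalg.det(S)
        mu = state.as_array()

        def integrand(b, i):
            d = np.array([i, b]) - mu
            dens = np.exp(-0.5 * d @ Si @ d) / (2 * np.pi * np.sqrt(det))
            return dens * individual_fitness(i + b * n, b, n, p)

        si, sb = np.sqrt(S[0, 0]), np.sqrt(S[1, 1])
        expected, _ = integrate.dblquad(
            integrand, mu[0] - 10 * si, mu[0] + 10 * si, mu[1] - 10 * sb, mu[1] + 10 * sb,
            epsabs=1e-12, epsrel=1e-12)
        assert env_mean_fitness(n, state, p) == pytest.approx(expected, rel=1e-8)

    def test_positive_for_extreme_states(self, ref_params):
        assert env_mean_fitness(3.0, PopulationState(40.0, 5.0), ref_params) > 0


class TestSelectionGradients:
    def test_intercept_gradient_vanishes_at_optimum_center(self, ref_params):
        state = PopulationState(ref_params.A, -0.7)
        assert selection_gradient_intercept(0.0, state, ref_params) == pytest.approx(0.0, abs=1e-14)

    def test_slope_gradient_vanishes_without_plasticity_or_mismatch(self, ref_params):
        state = PopulationState(ref_params.A, 0.0)
        assert selection_gradient_slope(0.0, state, ref_params) == pytest.approx(0.0, abs=1e-14)

    def test_pure_cost_of_plasticity_is_negative(self, ref_params):
        """At n=0 with the mean on the optimum, selection on a positive mean
        slope comes only from the cost term and must push it down."""
        state = PopulationState(ref_params.A, 1.0)
        assert selection_gradient_slope(0.0, state, ref_params) < 0

    def test_univariate_stabilizing_selection_limit(self):
        """With no slope variance, no cost, and a flat optimum, the intercept
        gradient is the textbook (theta - mu)/(sigma^2 + omega^2)."""
        p = ModelParams(B=0.0, A=0.0, omega_b2=1e12, sigma_ab2=TINY, sigma_eb2=0.0)
        state = PopulationState(p.A - 1.0, 0.0)
        expected = 1.0 / (p.sigma_i2 + p.omega_y2)
        assert selection_gradient_intercept(0.0, state, p) == pytest.approx(expected, rel=1e-6)

    def test_closed_forms_match_finite_differences(self, rng):
        """Rational closed forms vs central differences of ln Wbar(n)
        over 100 random parameter/state draws with zero correlation."""
        h = 1e-6
        for _ in range(100):
            p = random_valid_params(rng)
            state = random_state(rng)
            n = float(rng.normal(0, 1.5))
            grad = selection_gradients(n, state, p)
            for k, (di, db) in enumerate([(h, 0.0), (0.0, h)]):
                hi = np.log(env_mean_fitness(n, PopulationState(state.mu_i + di, state.mu_b + db), p))
                lo = np.log(env_mean_fitness(n, PopulationState(state.mu_i - di, state.mu_b - db), p))
                assert grad[k] == pytest.approx((hi - lo) / (2 * h), abs=1e-6)

    @pytest.mark.parametrize("rho", [0.5, -0.9])
    def test_correlated_gradients_match_finite_differences(self, rho, rng):
        h = 1e-6
        for _ in range(20):
            p = random_valid_params(rng, rho=rho)
            state = random_state(rng)
            n = float(rng.normal(0, 1.5))
            grad = selection_gradients(n, state, p)
            for k, (di, db) in enumerate([(h, 0.0), (0.0, h)]):
                hi = np.log(env_mean_fitness(n, PopulationState(state.mu_i + di, state.mu_b + db), p))
                lo = np.log(env_mean_fitness(n, PopulationState(state.mu_i - di, state.mu_b - db), p))
                assert grad[k] == pytest.approx((hi - lo) / (2 * h), abs=1e-6)

    def test_constant_variance_mode_refuses_correlation(self, rng):
        p = random_valid_params(rng, rho=0.5)
        with pytest.raises(ValueError, match="correlation"):
            selection_gradients(0.5, PopulationState(0, 0), p, mode="constant")


class TestResponses:
    def test_no_genetic_variance_no_response(self):
        p = ModelParams(sigma_ai2=0.0, sigma_ab2=0.0, sigma_ei2=1.0, sigma_eb2=1.0)
        r = response_in_environment(1.3, PopulationState(0.5, -0.5), p)
        assert (r.d_mu_i, r.d_mu_b) == (0.0, 0.0)

    def test_diagonal_g_matrix(self, ref_params):
        state = PopulationState(0.2, -0.4)
        n = 1.0
        r = response_in_environment(n, state, ref_params)
        assert r.d_mu_i == pytest.approx(
            ref_params.sigma_ai2 * selection_gradient_intercept(n, state, ref_params))
        assert r.d_mu_b == pytest.approx(
            ref_params.sigma_ab2 * selection_gradient_slope(n, state, ref_params))

    def test_matches_explicit_matrix_product(self, rng):
        p = random_valid_params(rng, rho=0.4)
        state = random_state(rng)
        n = 1.0
        r = response_in_environment(n, state, p)
        expected = p.genetic_cov() @ selection_gradients(n, state, p)
        assert r.as_array() == pytest.approx(expected)


class TestGlobalMeanFitnessAndTotalResponse:
    def test_flat_fitness_gives_one(self):
        p = ModelParams(alpha=0.0, omega_b2=1e12,
                        sigma_ai2=TINY, sigma_ei2=0, sigma_ab2=TINY, sigma_eb2=0)
        w = global_mean_fitness(PopulationState(p.A, p.B), p, check=True)
        assert w == pytest.approx(1.0, rel=1e-9)

    def test_lognormal_mean_when_selection_off(self):
        p = ModelParams(alpha=1.0, omega_y2=1e12, omega_b2=1e12, sigma_n2=1.0)
        w = global_mean_fitness(PopulationState(0.0, 0.0), p, check=True)
        assert w == pytest.approx(np.exp(0.5), rel=1e-8)

    def test_matches_adaptive_quadrature_oracle(self, ref_params):
        state = PopulationState(0.0, -0.5)
        sd = np.sqrt(ref_params.sigma_n2)

        def integrand(n):
            dens = np.exp(-0.5 * (n / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
            return dens * env_mean_fitness(n, state, ref_params)

        expected, _ = integrate.quad(integrand, -10 * sd, 10 * sd, epsabs=1e-13, epsrel=1e-13)
        assert global_mean_fitness(state, ref_params) == pytest.approx(expected, rel=1e-10)

    def test_environment_weights_normalized(self, rng):
        for _ in range(10):
            p = random_valid_params(rng)
            _, w = environment_weights(random_state(rng), p)
            assert w.sum() == pytest.approx(1.0, abs=1e-8)

    def test_zero_at_equilibrium(self, ref_params):
        sol = solve_equilibrium_numeric(ref_params)
        r = total_response(sol.state(), ref_params)
        assert abs(r.d_mu_i) < 1e-8 and abs(r.d_mu_b) < 1e-8

    def test_zero_under_symmetric_selection(self):
        p = ModelParams(alpha=0.0, B=0.0)
        r = total_response(PopulationState(p.A, 0.0), p)
        assert abs(r.d_mu_i) < 1e-12 and abs(r.d_mu_b) < 1e-12

    def test_intercept_response_sign_flips_with_displacement(self):
        """With symmetric selection (alpha=0, B=0, mu_b=0) the total intercept
        response restores the mean toward the optimum from either side."""
        p = ModelParams(alpha=0.0, B=0.0)
        up = total_response(PopulationState(p.A - 1.0, 0.0), p)
        down = total_response(PopulationState(p.A + 1.0, 0.0), p)
        assert up.d_mu_i > 0 > down.d_mu_i

    def test_fixed_maladaptive_slope_pushes_mean_late(self):
        """Fixed slope -1 with a flat optimum: hard selection pushes the mean
        breeding date past the optimum (the classic later-than-optimal shift)."""
        p = ModelParams(B=0.0, alpha=1.0, sigma_ab2=0.0, sigma_eb2=0.0)
        r = total_response(PopulationState(p.A, -1.0), p)
        assert r.d_mu_i > 0

    def test_soft_selection_reduction(self):
        """When Wbar(n) is constant in n the weighted total response equals
        the unweighted environment average of the per-environment responses."""
        p = ModelParams(alpha=0.0, B=-1.0, omega_b2=1e12)
        state = PopulationState(p.A, p.B)  # perfect plasticity, no cost
        # constant-variance mode: Wbar(n) is exactly constant here
        quad = QuadratureSpec()
        nodes, w = quad.nodes_weights(p.sigma_n2)
        resp = np.array([response_in_environment(n, state, p, mode="constant").as_array()
                         for n in nodes])
        unweighted = w @ resp
        weighted = total_response(state, p, quad, mode="constant").as_array()
        assert weighted == pytest.approx(unweighted, abs=1e-8)


class TestPhenotypicVariance:
    def test_at_reference_environment(self, ref_params):
        assert phenotypic_variance(0.0, ref_params) == pytest.approx(ref_params.sigma_i2)

    def test_quadratic_in_n(self):
        p = ModelParams(sigma_ai2=1.0, sigma_ei2=0.0, sigma_ab2=1.0, sigma_eb2=0.0)
        assert phenotypic_variance(2.0, p) == pytest.approx(5.0)

    def test_constant_approximation(self):
        p = ModelParams(sigma_n2=1.0)
        assert constant_phenotypic_variance(p) == pytest.approx(2.0)

    @given(n=st.floats(-4, 4))
    @settings(derandomize=True, max_examples=30)
    def test_consistency_with_covariance_matrix(self, n):
        p = ModelParams(sigma_ai2=0.7, sigma_ab2=0.9, rho_ib=0.3)
        v = np.array([1.0, n])
        assert phenotypic_variance(n, p) == pytest.approx(v @ p.phenotypic_cov() @ v)
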