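"""Algebra of fixed points, stability, thresholds and regime labels."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radicon.model_core import (
    ModelParameters,
    PopulationState,
    classify_regime,
    critical_threshold,
    equilibrium_roots,
    min_core_engagement,
    rhs,
    stability,
)

valid_params = st.builds(
    ModelParameters,
    sigma_I=st.floats(0.001, 0.999),
    alpha=st.floats(0.001, 50.0),
    beta=st.floats(0.001, 50.0),
)


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"sigma_I": -0.1, "alpha": 1, "beta": 1},
            {"sigma_I": 1.2, "alpha": 1, "beta": 1},
            {"sigma_I": 0.3, "alpha": -1, "beta": 1},
            {"sigma_I": 0.3, "alpha": 1, "beta": -2},
            {"sigma_I": float("nan"), "alpha": 1, "beta": 1},
            {"sigma_I": 0.3, "alpha": float("inf"), "beta": 1},
        ],
    )
    def test_bad_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParameters(**kwargs)

    def test_state_rejects_negative_densities(self):
        with pytest.raises(ValueError):
            PopulationState(t=0.0, sigma_P=-0.01, sigma_O=0.5)

    def test_state_closure_check(self):
        state = PopulationState(t=0.0, sigma_P=0.4, sigma_O=0.3)
        state.check_closure(0.3)
        with pytest.raises(ValueError):
            state.check_closure(0.5)


class TestRhs:
    @pytest.mark.parametrize(
        "sigma_I, alpha, beta, sigma_P, expected",
        [
            (0.3, 1.0, 1.0, 0.7, 0.0),    # at root p1
            (0.3, 1.0, 1.0, 0.3, 0.0),    # at root p2
            (0.3, 1.0, 1.0, 0.4, -0.03),  # 1*0.3*0.3 - 1*0.3*0.4
        ],
    )
    def test_pointwise_values(self, sigma_I, alpha, beta, sigma_P, expected):
        params = ModelParameters(sigma_I, alpha, beta)
        assert rhs(params, sigma_P) == pytest.approx(expected, abs=1e-15)

    def test_domain_error_outside_physical_range(self):
        params = ModelParameters(0.3, 1.0, 1.0)
        with pytest.raises(ValueError):
            rhs(params, 0.9)  # above 1 - sigma_I = 0.7

    @given(valid_params)
    @settings(max_examples=200, derandomize=True)
    def test_rhs_vanishes_at_both_roots(self, params):
        p1, p2 = equilibrium_roots(params)
        assert abs(rhs(params, p1)) < 1e-12
        if 0.0 <= p2 <= params.sigma_S:
            assert abs(rhs(params, p2)) < 1e-12

    @given(valid_params, st.floats(0.0, 1.0))
    @settings(max_examples=200, derandomize=True)
    def test_rhs_equals_factored_form(self, params, frac):
        sigma_P = frac * params.sigma_S
        p1, p2 = equilibrium_roots(params)
        factored = params.beta * (p1 - sigma_P) * (p2 - sigma_P)
        assert rhs(params, sigma_P) == pytest.approx(factored, abs=1e-12)


class TestEquilibriumRoots:
    @pytest.mark.parametrize(
        "sigma_I, alpha, beta, expected",
        [
            (0.1, 22.0, 2.0, (0.9, 1.1)),
            (0.0, 7.0, 3.0, (1.0, 0.0)),
            (0.28, 0.5, 0.5, (0.72, 0.28)),
        ],
    )
    def test_root_values(self, sigma_I, alpha, beta, expected):
        p1, p2 = equilibrium_roots(ModelParameters(sigma_I, alpha, beta))
        assert p1 == pytest.approx(expected[0], abs=1e-14)
        assert p2 == pytest.approx(expected[1], abs=1e-14)

    @given(valid_params)
    @settings(max_examples=200, derandomize=True)
    def test_roots_solve_the_equilibrium_quadratic(self, params):
        a, b, s = params.alpha, params.beta, params.sigma_I
        for p in equilibrium_roots(params):
            quad = b * p**2 - (a * s + b * (1 - s)) * p + a * s * (1 - s)
            assert abs(quad) < 1e-10

    def test_beta_zero_flags_degenerate_second_root(self):
        p1, p2 = equilibrium_roots(ModelParameters(0.3, 1.0, 0.0))
        assert p1 == 0.7
        assert math.isnan(p2)


class TestStability:
    def test_extinction_scenario_selects_opponent_free_root(self):
        rep = stability(ModelParameters(0.1, 22.0, 2.0))
        assert rep.stable_root == "p1"
        assert rep.sigma_O_eq == 0.0
        assert rep.sigma_P_eq == pytest.approx(0.9)
        assert rep.thwarted

    def test_marginal_case_equal_roots(self):
        rep = stability(ModelParameters(0.5, 2.0, 2.0))
        assert rep.stable_root == "marginal"
        assert rep.marginal
        assert rep.lambda1 == rep.lambda2 == 0.0
        assert rep.p1 == rep.p2 == 0.5

    def test_coexistence_scenario(self):
        rep = stability(ModelParameters(0.1, 12.0, 2.0))
        assert rep.stable_root == "p2"
        assert rep.sigma_P_eq == pytest.approx(0.6)
        assert rep.sigma_O_eq == pytest.approx(0.3)
        assert not rep.thwarted

    def test_beta_zero_pure_decay(self):
        rep = stability(ModelParameters(0.3, 1.0, 0.0))
        assert rep.degenerate_beta0
        assert rep.sigma_O_eq == 0.0
        assert rep.sigma_P_eq == pytest.approx(0.7)
        assert rep.lambda1 == pytest.approx(-0.3)  # decay rate alpha*sigma_I

    @given(valid_params)
    @settings(max_examples=300, derandomize=True)
    def test_eigenvalue_antisymmetry_and_closure(self, params):
        rep = stability(params)
        assert rep.lambda1 + rep.lambda2 == 0.0
        assert rep.lambda1 == pytest.approx(params.beta * (rep.p1 - rep.p2), rel=1e-12)
        total = params.sigma_I + rep.sigma_P_eq + rep.sigma_O_eq
        assert total == pytest.approx(1.0, abs=1e-12)

    @given(valid_params)
    @settings(max_examples=300, derandomize=True)
    def test_opponent_free_iff_above_threshold(self, params):
        rep = stability(params)
        above = params.sigma_I >= critical_threshold(params) - 1e-12
        if rep.sigma_O_eq == 0.0:
            assert above
        else:
            assert not rep.thwarted
            expected = 1.0 - ((params.alpha + params.beta) / params.beta) * params.sigma_I
            assert rep.sigma_O_eq == pytest.approx(expected, abs=1e-12)


class TestCriticalThreshold:
    @pytest.mark.parametrize(
        "alpha, beta, expected",
        [(3.0, 3.0, 0.5), (22.0, 2.0, 1.0 / 12.0), (0.0, 5.0, 1.0)],
    )
    def test_values(self, alpha, beta, expected):
        assert critical_threshold(ModelParameters(0.3, alpha, beta)) == pytest.approx(
            expected
        )

    def test_undefined_for_frozen_dynamics(self):
        with pytest.raises(ValueError):
            critical_threshold(ModelParameters(0.3, 0.0, 0.0))


class TestMinCoreEngagement:
    @pytest.mark.parametrize(
        "sigma_I, beta, expected",
        [(0.5, 2.0, 2.0), (1.0, 7.0, 0.0), (0.25, 1.0, 3.0)],
    )
    def test_values(self, sigma_I, beta, expected):
        assert min_core_engagement(sigma_I, beta) == pytest.approx(expected)

    def test_domain_error_at_zero_core(self):
        with pytest.raises(ValueError):
            min_core_engagement(0.0, 1.0)

    @given(st.floats(0.01, 1.0), st.floats(0.01, 20.0))
    @settings(max_examples=200, derandomize=True)
    def test_inverts_critical_threshold(self, sigma_I, beta):
        """Setting alpha = alpha* makes sigma_I the critical fraction exactly."""
        alpha_star = min_core_engagement(sigma_I, beta)
        I_c = critical_threshold(ModelParameters(sigma_I, alpha_star, beta))
        assert I_c == pytest.approx(sigma_I, rel=1e-12)


class TestClassifyRegime:
    @pytest.mark.parametrize(
        "sigma_I, alpha, beta, case, thwarted",
        [
            (0.6, 0.5, 2.0, "case1", False),  # core majority, beta >> alpha
            (0.6, 2.0, 0.5, "case1", True),
            (0.5, 2.0, 2.0, "case2", True),   # marginal boundary counts as thwarted
            (0.28, 0.5, 0.5, "case3", False),
            (0.1, 22.0, 2.0, "case3", True),
        ],
    )
    def test_labels(self, sigma_I, alpha, beta, case, thwarted):
        regime, flag = classify_regime(ModelParameters(sigma_I, alpha, beta))
        assert regime == case
        assert flag is thwarted

    @given(valid_params)
    @settings(max_examples=500, derandomize=True)
    def test_thwarted_flag_consistency(self, params):
        """Thwarted <=> p1 <= p2 <=> sigma_I >= beta/(alpha+beta), up to ties."""
        _, flag = classify_regime(params)
        p1, p2 = equilibrium_roots(params)
        if abs(p1 - p2) > 1e-9:
            assert flag == (p1 < p2)
            assert flag == (
                params.sigma_I > params.beta / (params.alpha + params.beta)
            )
        else:
            assert flag  # marginal: thwarted in the limit
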