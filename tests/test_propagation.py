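"""Tests of the analytic variance/covariance propagation."""

import numpy as np
import pytest

from saccnoise.dynamics import LoopParameters, PlantParameters, TimeGrid, impulse_responses
from saccnoise.propagation import (
    MeanFamily,
    PredictionEngine,
    on_noise_var_cov,
    pbn_power_density,
    pbn_var_cov,
    planning_derivative,
    planning_var_cov,
    total_prediction,
)


@pytest.fixture(scope="module")
def family(ms):
    return MeanFamily.from_model(ms, 10.1)


@pytest.fixture(scope="module")
def engine(family):
    return PredictionEngine(family)


class TestPlanningNoise:
    def test_scaling_family_gives_shape_exactly(self):
        s = np.linspace(0, 1, 100) ** 2
        d = planning_derivative(12.5 * s, 7.5 * s, delta=5.0)
        np.testing.assert_allclose(d, s, rtol=1e-12)

    def test_derivative_is_one_at_movement_end(self, family):
        d = planning_derivative(family.y_norm_plus, family.y_norm_minus, family.delta)
        assert d[-1] == pytest.approx(1.0, abs=1e-3)

    def test_wide_quotient_matches_fine_quotient(self, ms, family):
        """Δ = 5 deg difference quotient vs a Δ = 0.1 deg one: the
        self-similar family keeps them within 2%."""
        fine = MeanFamily.from_model(ms, 10.1, delta=0.1)
        d5 = planning_derivative(family.y_norm_plus, family.y_norm_minus, 5.0)
        d01 = planning_derivative(fine.y_norm_plus, fine.y_norm_minus, 0.1)
        mask = d01 > 0.05
        assert np.max(np.abs(d5[mask] - d01[mask]) / d01[mask]) < 0.02

    def test_zero_coefficient_gives_zero_trajectories(self, family):
        d = planning_derivative(family.y_norm_plus, family.y_norm_minus, family.delta)
        var, cov = planning_var_cov(d, 0.0, family.A_bar)
        assert np.all(var == 0.0) and np.all(cov == 0.0)

    def test_endpoint_variance_equals_sigma_squared(self, family):
        """End-point planning variance is k_A²·Ā²: 0.106²·10.1² ≈ 1.146."""
        d = planning_derivative(family.y_norm_plus, family.y_norm_minus, family.delta)
        var, cov = planning_var_cov(d, 0.106, 10.1)
        assert var[-1] == pytest.approx(0.106**2 * 10.1**2, rel=2e-3)
        assert 0.106**2 * 10.1**2 == pytest.approx(1.146, abs=5e-4)

    def test_implied_correlation_is_unity(self, family):
        d = planning_derivative(family.y_norm_plus, family.y_norm_minus, family.delta)
        var, cov = planning_var_cov(d, 0.1, 10.1)
        mask = d > 1e-6
        rho = cov[mask] / np.sqrt(var[mask] * var[-1])
        np.testing.assert_allclose(rho, 1.0, atol=1e-12)


class TestONNoise:
    def test_zero_coefficient(self, plant, family):
        irs = impulse_responses(plant, LoopParameters(g=0.0), family.grid)
        var, cov, Q = on_noise_var_cov(family.C3_bar, None, 0.0, irs, family.D_bar)
        assert np.all(var == 0.0) and np.all(Q == 0.0)

    def test_no_upstream_noise_reduces_to_squared_command(self, plant, family):
        """With var_C3 = 0 the power density is the classical
        signal-dependent form k²·C̄3²."""
        irs = impulse_responses(plant, LoopParameters(g=0.0), family.grid)
        _, _, Q = on_noise_var_cov(family.C3_bar, None, 0.05, irs, family.D_bar)
        np.testing.assert_allclose(Q, 0.05**2 * family.C3_bar**2, rtol=1e-12)

    def test_covariance_meets_variance_at_end(self, plant, family):
        irs = impulse_responses(plant, LoopParameters(g=0.0), family.grid)
        var, cov, _ = on_noise_var_cov(family.C3_bar, None, 0.05, irs, family.D_bar)
        assert cov[-1] == pytest.approx(var[-1], rel=1e-12)


class TestPBNPowerDensity:
    def test_zero_coefficient(self, family):
        irs_m = impulse_responses(PlantParameters(), LoopParameters(g=240.0), family.grid).m
        assert np.all(pbn_power_density(family.C2_bar, 0.0, irs_m, family.grid) == 0.0)

    def test_initial_value(self, family):
        m = impulse_responses(PlantParameters(), LoopParameters(g=240.0), family.grid).m
        Q = pbn_power_density(family.C2_bar, 0.03, m, family.grid)
        assert Q[0] == pytest.approx(0.03**2 * family.C2_bar[0] ** 2, abs=1e-15)

    def test_open_loop_closed_form(self, family):
        """g = 0 collapses the recursion to k²·C̄2²/(1 − k²·step)."""
        grid = family.grid
        m = np.zeros(grid.n_samples)
        m[0] = 1.0
        k = 0.05
        Q = pbn_power_density(family.C2_bar, k, m, grid)
        np.testing.assert_allclose(
            Q[1:], k**2 * family.C2_bar[1:] ** 2 / (1 - k**2 * grid.step), rtol=1e-12
        )

    def test_recursion_solves_volterra_fixed_point(self, family):
        """Oracle: iterate the Volterra equation to its fixed point and
        compare with the forward recursion."""
        grid = family.grid
        h = grid.step
        m = impulse_responses(PlantParameters(), LoopParameters(g=240.0), family.grid).m
        k = 0.028
        Q = pbn_power_density(family.C2_bar, k, m, grid)
        msq = np.zeros(grid.n_samples)
        msq[0] = m[0] ** 2 * h  # direct feedthrough weighted by the step
        msq[1:] = (m[1:] / h) ** 2 * h
        Q_it = k**2 * family.C2_bar**2
        for _ in range(200):
            conv = np.convolve(Q_it, msq)[: grid.n_samples]
            Q_it = k**2 * (family.C2_bar**2 + conv)
        assert np.max(np.abs(Q_it - Q)) < 1e-10 * max(Q.max(), 1.0)

    def test_ill_posed_convention_rejected(self, family):
        m = np.zeros(family.grid.n_samples)
        m[0] = 100.0  # a 1/step-style delta convention would break Eq's denominator
        with pytest.raises(ValueError, match="ill-posed"):
            pbn_power_density(family.C2_bar, 0.5, m, family.grid)


class TestPBNTrajectories:
    def test_zero_power_density(self, plant, family):
        irs = impulse_responses(plant, LoopParameters(g=240.0), family.grid)
        var, cov, vc2, vc3 = pbn_var_cov(np.zeros(family.grid.n_samples), irs, family.D_bar)
        for arr in (var, cov, vc2, vc3):
            assert np.all(arr == 0.0)

    def test_control_parameters_give_bell_shape(self, engine):
        pred = engine.predict(0.0, 0.0, 0.028, 240.0)
        v = pred.components["PBN"].var
        peak = int(np.argmax(v))
        assert 0 < peak < 99
        assert v[-1] < v[peak]


class TestTotalPrediction:
    def test_all_zero_coefficients(self, engine):
        pred = engine.predict(0.0, 0.0, 0.0, 240.0)
        assert np.all(pred.var == 0.0) and np.all(pred.cov == 0.0)

    def test_superposition_is_exact(self, engine):
        pred = engine.predict(0.106, 0.02, 0.028, 240.0)
        total_var = sum(c.var for c in pred.components.values())
        total_cov = sum(c.cov for c in pred.components.values())
        np.testing.assert_array_equal(pred.var, total_var)
        np.testing.assert_array_equal(pred.cov, total_cov)

    def test_correlation_is_one_at_end(self, engine):
        pred = engine.predict(0.106, 0.0, 0.028, 240.0)
        assert pred.rho[-1] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("source", ["planning", "ON"])
    def test_doubling_k_quadruples_feedforward_sources(self, engine, source):
        base = {"planning": (0.1, 0.0, 0.0, 240.0),
                "ON": (0.0, 0.05, 0.0, 240.0)}[source]
        doubled = tuple(2 * v if i < 3 else v for i, v in enumerate(base))
        v1 = engine.predict(*base).components[source].var
        v2 = engine.predict(*doubled).components[source].var
        np.testing.assert_allclose(v2, 4.0 * v1, rtol=1e-9)

    def test_pbn_scaling_quadratic_only_in_small_k_limit(self, engine):
        """The loop-injected power density solves Q = k²(C̄2² + ∫Q·m²), so
        doubling k quadruples the variance only asymptotically as k → 0; at
        realistic k the self-referential feedback makes it super-quadratic."""
        v_small_1 = engine.predict(0.0, 0.0, 0.002, 240.0).components["PBN"].var
        v_small_2 = engine.predict(0.0, 0.0, 0.004, 240.0).components["PBN"].var
        np.testing.assert_allclose(v_small_2[1:], 4.0 * v_small_1[1:], rtol=0.01)
        v1 = engine.predict(0.0, 0.0, 0.028, 240.0).components["PBN"].var
        v2 = engine.predict(0.0, 0.0, 0.056, 240.0).components["PBN"].var
        assert v2[-1] > 4.5 * v1[-1]

    def test_step_halving_convergence(self, ms):
        """Halving the grid step changes the predictions by the expected
        discretization orders: <2% for the feedforward (ON) component and
        <5% for the loop-filtered (PBN) component, whose explicit-Euler
        loop recursion carries an O(g·step) error."""
        p1 = total_prediction((0.1, 0.02, 0.028, 240.0), MeanFamily.from_model(ms, 10.1, step=5e-4))
        p2 = total_prediction((0.1, 0.02, 0.028, 240.0), MeanFamily.from_model(ms, 10.1, step=2.5e-4))
        for src, tol in (("planning", 0.02), ("ON", 0.02), ("PBN", 0.05)):
            a = p1.components[src].var
            b = p2.components[src].var
            assert np.max(np.abs(a - b)) < tol * b.max()

    def test_variant_shape_dichotomy(self, engine):
        """Planning and ON variance trajectories increase monotonically;
        the PBN trajectory does not (interior maximum)."""
        pred = engine.predict(0.106, 0.02, 0.028, 240.0)
        for src in ("planning", "ON"):
            assert np.min(np.diff(pred.components[src].var)) >= -1e-9 * pred.components[src].var.max()
        assert np.min(np.diff(pred.components["PBN"].var)) < 0
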