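"""Objectives, weights, horizon selection and the bounded optimizer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedtrain.estimation import (
    EstimationProblem,
    MeasurementWindow,
    PriorInfo,
    estimate,
    forgetting_weight,
    measurement_weights,
    mhe_objective,
    parameter_penalty,
    penalty_weight,
    scale_parameters,
    select_horizon,
    unscale_parameters,
    wlse_objective,
)
from seedtrain.kinetic_model import FreeParameterSpec


def unit_spec(n=1, lower=0.0, upper=1.0):
    return FreeParameterSpec(
        tuple(f"p{i}" for i in range(n)),
        np.full(n, lower),
        np.full(n, upper),
    )


def make_problem(y_m, y_of_p, w_m=None, spec=None, prior=None, start=None):
    y_m = np.asarray(y_m, dtype=float)
    spec = spec if spec is not None else unit_spec()
    window = MeasurementWindow(
        times=np.arange(y_m.shape[0], dtype=float),
        y_m=y_m,
        variable_names=tuple(f"v{j}" for j in range(y_m.shape[1])),
        w_m=w_m,
    )
    return EstimationProblem(
        window=window,
        free_spec=spec,
        fixed_params=None,
        start_values=start if start is not None else (spec.lower + spec.upper) / 2,
        simulator=y_of_p,
        prior=prior,
    )


class TestMeasurementWeights:
    def test_inverse_of_column_maximum(self):
        w = measurement_weights(np.array([[2.0], [4.0]]))
        np.testing.assert_allclose(w, [[0.25], [0.25]])

    def test_constant_column(self):
        w = measurement_weights(np.array([[3.0], [3.0], [3.0]]))
        np.testing.assert_allclose(w, 1 / 3)

    def test_per_column_scaling(self):
        y = np.array([[10.0, 0.5], [5.0, 0.25]])
        w = measurement_weights(y)
        np.testing.assert_allclose(w[:, 0], 0.1)
        np.testing.assert_allclose(w[:, 1], 2.0)

    def test_all_missing_column_rejected(self):
        with pytest.raises(ValueError):
            measurement_weights(np.array([[1.0, np.nan], [2.0, np.nan]]))


class TestWlseObjective:
    def test_perfect_fit_is_zero(self):
        y_m = np.array([[2.0], [4.0]])
        prob = make_problem(y_m, lambda p: y_m)
        assert wlse_objective(np.array([0.5]), prob) == 0.0

    def test_hand_evaluated_value(self):
        """One variable, two points, weights 1/4: J = (2-1)^2 / 4 = 0.25."""
        y_m = np.array([[2.0], [4.0]])
        prob = make_problem(y_m, lambda p: np.array([[1.0], [4.0]]))
        assert wlse_objective(np.array([0.5]), prob) == pytest.approx(0.25)

    def test_quadratic_homogeneity(self):
        y_m = np.array([[2.0], [4.0]])
        prob1 = make_problem(y_m, lambda p: np.array([[1.0], [3.0]]))
        prob2 = make_problem(y_m, lambda p: np.array([[0.0], [2.0]]))  # doubled residuals
        J1 = wlse_objective(np.array([0.5]), prob1)
        J2 = wlse_objective(np.array([0.5]), prob2)
        assert J2 == pytest.approx(4 * J1)

    def test_missing_entries_excluded(self):
        y_m = np.array([[2.0, np.nan], [4.0, 5.0]])
        w_m = np.array([[0.25, 0.2], [0.25, 0.2]])
        prob = make_problem(y_m, lambda p: np.array([[1.0, 99.0], [4.0, 5.0]]), w_m=w_m)
        assert wlse_objective(np.array([0.5]), prob) == pytest.approx(0.25)


class TestParameterScaling:
    def test_bounds_map_to_unit_interval(self):
        spec = unit_spec(3, lower=2.0, upper=6.0)
        np.testing.assert_allclose(scale_parameters(spec.lower, spec), 0.0)
        np.testing.assert_allclose(scale_parameters(spec.upper, spec), 1.0)
        np.testing.assert_allclose(scale_parameters(np.full(3, 4.0), spec), 0.5)

    def test_affine_value(self):
        spec = unit_spec(1, lower=1.0, upper=3.0)
        assert scale_parameters(np.array([2.5]), spec)[0] == pytest.approx(0.75)

    def test_roundtrip(self):
        spec = unit_spec(4, lower=0.5, upper=2.0)
        p = np.array([0.6, 1.0, 1.5, 2.0])
        np.testing.assert_allclose(unscale_parameters(scale_parameters(p, spec), spec), p)


class TestParameterPenalty:
    def test_zero_at_prior(self):
        spec = unit_spec(7)
        p = np.full(7, 0.3)
        assert parameter_penalty(p, p, spec) == 0.0

    def test_single_component_half_interval(self):
        spec = unit_spec(7)
        p_hat = np.full(7, 0.25)
        p = p_hat.copy()
        p[0] = 0.75  # scaled difference 0.5
        assert parameter_penalty(p, p_hat, spec, gamma=1.0) == pytest.approx(0.5 / 7)

    def test_all_components_full_interval(self):
        spec = unit_spec(7)
        assert parameter_penalty(
            np.ones(7), np.zeros(7), spec, gamma=1.0
        ) == pytest.approx(np.sqrt(7) / 7)


class TestHorizonWeights:
    @pytest.mark.parametrize("n,expected", [(2, 2.0), (4, 1.0), (8, 0.5)])
    def test_forgetting_weight(self, n, expected):
        assert forgetting_weight(n) == pytest.approx(expected)

    @pytest.mark.parametrize("n,expected", [(1, 1.0), (2, 0.5), (4, 0.25)])
    def test_penalty_weight(self, n, expected):
        assert penalty_weight(n) == pytest.approx(expected)

    def test_zero_horizon_rejected(self):
        with pytest.raises(ValueError):
            forgetting_weight(0)
        with pytest.raises(ValueError):
            penalty_weight(0)

    def test_forgetting_weight_decreases(self):
        w = [forgetting_weight(n) for n in range(1, 20)]
        assert np.all(np.diff(w) < 0)


class TestMheObjective:
    def _prior(self, y_hat, w_p, c_dp, p_hat, gamma=1.0):
        return PriorInfo(p_hat=p_hat, y_hat=np.asarray(y_hat, float), w_p=w_p, c_dp=c_dp, gamma=gamma)

    def test_reduces_to_wlse_without_prior_terms(self):
        rng = np.random.default_rng(42)
        y_m = np.array([[2.0], [4.0]])
        sim = lambda p: np.array([[1.0 + p[0]], [4.0 - p[0]]])
        prior = self._prior(y_m, w_p=0.0, c_dp=0.0, p_hat=np.array([0.5]))
        prob = make_problem(y_m, sim, prior=prior)
        for _ in range(100):
            p = rng.uniform(0, 1, size=1)
            J_m = mhe_objective(p, prob)
            J_w = wlse_objective(p, prob)
            assert J_m == pytest.approx(J_w, rel=1e-12, abs=1e-15)

    def test_vanishes_at_prior(self):
        """At p = p_hat both prior terms are zero, leaving the WLSE part."""
        y_m = np.array([[2.0], [4.0]])
        sim = lambda p: np.array([[1.0 + p[0]], [4.0]])
        p_hat = np.array([0.5])
        prior = self._prior(sim(p_hat), w_p=2.0, c_dp=0.3, p_hat=p_hat)
        prob = make_problem(y_m, sim, prior=prior)
        assert mhe_objective(p_hat, prob) == pytest.approx(
            wlse_objective(p_hat, prob)
        )

    def test_hand_evaluated_value(self):
        """wlse 0.25 + forgetting 2*((1-2)^2+(4-3)^2) + penalty 0.01 = 4.26."""
        y_m = np.array([[2.0], [4.0]])
        sim = lambda p: np.array([[1.0], [4.0]])
        # penalty: 1 free parameter on [0,1], p=0.1 vs p_hat=0.0, gamma=1
        # => dp = 0.1; with c_dp = 0.1 the term is 0.01
        prior = self._prior(
            np.array([[2.0], [3.0]]), w_p=2.0, c_dp=0.1, p_hat=np.array([0.0])
        )
        prob = make_problem(y_m, sim, prior=prior, start=np.array([0.0]))
        assert mhe_objective(np.array([0.1]), prob) == pytest.approx(4.26)

    def test_measured_forgetting_form_constant_in_p(self):
        y_m = np.array([[2.0], [4.0]])
        sim = lambda p: np.array([[1.0 + p[0]], [4.0 - p[0]]])
        prior = self._prior(np.array([[2.0], [3.0]]), w_p=2.0, c_dp=0.0, p_hat=np.array([0.5]))
        prob = make_problem(y_m, sim, prior=prior)
        offset0 = mhe_objective(np.array([0.2]), prob, forgetting_form="measured") - wlse_objective(
            np.array([0.2]), prob
        )
        offset1 = mhe_objective(np.array([0.8]), prob, forgetting_form="measured") - wlse_objective(
            np.array([0.8]), prob
        )
        assert offset0 == pytest.approx(offset1)
        assert offset0 == pytest.approx(2.0 * ((2 - 2) ** 2 + (4 - 3) ** 2))

    def test_penalty_monotone_in_parameter_distance(self):
        y_m = np.array([[2.0], [4.0]])
        sim = lambda p: y_m  # model values held fixed
        prior = self._prior(y_m, w_p=1.0, c_dp=0.5, p_hat=np.array([0.5]))
        prob = make_problem(y_m, sim, prior=prior)
        dists = np.linspace(0, 0.5, 10)
        J = [mhe_objective(np.array([0.5 + d]), prob) for d in dists]
        assert np.all(np.diff(J) > 0)


class TestSelectHorizon:
    def test_growing(self):
        assert select_horizon(range(10), 3, "growing") == [0, 1, 2, 3]

    def test_moving_fixed_length(self):
        assert select_horizon(range(10), 4, "moving", fixed_length=3) == [2, 3, 4]

    def test_moving_truncated_at_start(self):
        assert select_horizon(range(10), 1, "moving", fixed_length=4) == [0, 1]

    def test_per_scale_growing(self):
        scale_map = [0, 0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2]
        assert select_horizon(range(13), 6, "per_scale_growing", scale_map=scale_map) == [5, 6]

    def test_no_estimation_before_second_point(self):
        with pytest.raises(ValueError):
            select_horizon(range(10), 0, "growing")


class TestEstimate:
    def _quadratic_problem(self, target=0.7):
        y_m = np.array([[1.0], [1.0]])
        sim = lambda p: np.array([[1.0 + (p[0] - target)], [1.0 - (p[0] - target)]])
        return make_problem(y_m, sim, start=np.array([0.2]))

    def test_finds_known_minimum(self):
        prob = self._quadratic_problem(0.7)
        res = estimate(prob, "wlse")
        assert res.p_opt[0] == pytest.approx(0.7, abs=1e-4)
        assert res.converged

    def test_objective_never_worse_than_start(self):
        prob = self._quadratic_problem(0.7)
        res = estimate(prob, "wlse", n_starts=1, max_evals=60)
        J_start = wlse_objective(prob.start_values, prob)
        assert res.J_opt <= J_start + 1e-15

    def test_start_at_optimum_stays(self):
        prob = self._quadratic_problem(0.2)
        prob.start_values = np.array([0.2])
        res = estimate(prob, "wlse")
        assert res.J_opt <= wlse_objective(np.array([0.2]), prob) + 1e-15
        assert res.p_opt[0] == pytest.approx(0.2, abs=1e-4)

    def test_mhe_window_matching_prior_returns_prior(self):
        """If the data equal the prior simulation, p_hat is a global minimum."""
        target = 0.4
        sim = lambda p: np.array([[1.0 + (p[0] - target)], [2.0 + 2 * (p[0] - target)]])
        p_hat = np.array([target])
        y_m = sim(p_hat)
        prior = PriorInfo(p_hat=p_hat, y_hat=sim(p_hat), w_p=2.0, c_dp=0.5)
        prob = make_problem(y_m, sim, prior=prior, start=np.array([0.9]))
        res = estimate(prob, "mhe")
        assert res.p_opt[0] == pytest.approx(target, abs=1e-3)

    def test_variable_reordering_invariance(self):
        y_m = np.array([[2.0, 10.0], [4.0, 20.0]])
        target = 0.6

        def sim(p):
            return np.array(
                [[2.0 + (p[0] - target), 10.0], [4.0, 20.0 + (p[0] - target)]]
            )

        def sim_swapped(p):
            return sim(p)[:, ::-1].copy()

        prob1 = make_problem(y_m, sim, start=np.array([0.1]))
        prob2 = make_problem(y_m[:, ::-1].copy(), sim_swapped, start=np.array([0.1]))
        r1 = estimate(prob1, "wlse")
        r2 = estimate(prob2, "wlse")
        assert r1.p_opt[0] == pytest.approx(r2.p_opt[0], abs=1e-8)
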