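"""Binary SELM: kernels, the coordinate-descent dual solver, decisions."""

import numpy as np
import pytest

from conftest import dual_objective_of, make_qp, qp_oracle_grid, qp_oracle_lbfgsb
from eegselm.selm import (
    BinarySELMModel,
    KernelSpec,
    decision_value,
    decision_values,
    gram,
    init_state,
    kernel_eval,
    model_from_json,
    model_to_json,
    predict_binary,
    select_index,
    train_binary,
    update_multiplier,
)


class TestKernels:
    def test_gaussian_at_zero_distance_is_one(self, rng):
        x = rng.normal(size=8)
        assert kernel_eval(x, x, KernelSpec.gaussian(500.0)) == pytest.approx(1.0)

    def test_gaussian_analytic_value(self):
        x = np.zeros(1)
        y = np.array([np.sqrt(500.0)])  # squared distance exactly 500
        k = kernel_eval(x, y, KernelSpec.gaussian(500.0))
        assert k == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_polynomial_orthogonal_vectors(self):
        x = np.array([1.0, 0.0])
        y = np.array([0.0, 1.0])
        assert kernel_eval(x, y, KernelSpec.polynomial(4)) == pytest.approx(1.0)

    def test_polynomial_matches_formula(self, rng):
        x, y = rng.normal(size=3), rng.normal(size=3)
        assert kernel_eval(x, y, KernelSpec.polynomial(3)) == pytest.approx((1 + x @ y) ** 3)

    def test_laplacian_denominator_conventions(self):
        x, y = np.array([0.0]), np.array([2.0])
        k2 = kernel_eval(x, y, KernelSpec.laplacian(1.0))
        k1 = kernel_eval(x, y, KernelSpec.laplacian(1.0, denominator="sigma"))
        assert k2 == pytest.approx(np.exp(-1.0))
        assert k1 == pytest.approx(np.exp(-2.0))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            kernel_eval(np.zeros(2), np.zeros(3), KernelSpec.gaussian(1.0))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            KernelSpec.gaussian(0.0)
        with pytest.raises(ValueError):
            KernelSpec.polynomial(0)


class TestStateAndUpdates:
    def test_initial_state_all_scores_minus_one(self, rng):
        state = init_state(rng.normal(size=(5, 2)), [1, -1, 1, -1, 1], C=5.0, epsilon=1e-3)
        assert np.all(state.alpha == 0.0)
        assert np.all(state.g == -1.0)
        assert np.all(state.directions() == 1.0)
        assert np.all(state.scores() == -1.0)

    def test_single_sample_state(self, rng):
        state = init_state(rng.normal(size=(1, 2)), [1.0], C=1.0, epsilon=1e-3)
        assert state.alpha.shape == (1,)

    def test_bad_inputs_rejected(self, rng):
        X = rng.normal(size=(2, 2))
        with pytest.raises(ValueError):
            init_state(X, [1.0, 2.0], C=1.0, epsilon=1e-3)  # label outside {-1,+1}
        with pytest.raises(ValueError):
            init_state(X, [1.0, -1.0], C=0.0, epsilon=1e-3)
        with pytest.raises(ValueError):
            init_state(X, [1.0, -1.0], C=1.0, epsilon=0.0)

    def test_select_index_argmin_with_lowest_index_ties(self):
        state = init_state(np.zeros((3, 1)), [1.0, -1.0, 1.0], C=1.0, epsilon=1e-3)
        assert select_index(state) == 0  # J = (-1,-1,-1), tie -> lowest
        state.g = np.array([-0.5, -2.0, -0.1])
        assert select_index(state) == 1

    def test_select_index_stops_above_minus_epsilon(self):
        state = init_state(np.zeros((2, 1)), [1.0, -1.0], C=1.0, epsilon=1e-3)
        state.alpha = np.array([0.3, 0.2])
        state.g = np.array([0.01, 0.005])  # J = (-0.01, -0.005)? no: d=-sign(g)=-1
        # interior points with positive gradient move down: J = -g < -eps
        assert select_index(state) == 0
        state.g = np.array([-0.0005, -0.0002])  # J = (-5e-4, -2e-4) > -1e-3
        assert select_index(state) is None

    def test_one_sample_closed_form_update(self):
        # k(x,x)=1: first update drives alpha to 1 and the gradient to 0
        X = np.array([[2.0, 3.0]])
        state = init_state(X, [1.0], C=5.0, epsilon=1e-3)
        K = gram(X, X, KernelSpec.gaussian(500.0))
        update_multiplier(state, 0, K, mode="literal")
        assert state.alpha[0] == pytest.approx(1.0)
        assert state.g[0] == pytest.approx(0.0)
        assert select_index(state) is None

    def test_clipping_at_upper_and_lower_bounds(self):
        X = np.array([[0.0]])
        K = np.array([[1.0]])
        state = init_state(X, [1.0], C=5.0, epsilon=1e-3)
        state.g = np.array([-7.3])  # unconstrained step lands at 7.3
        update_multiplier(state, 0, K)
        assert state.alpha[0] == 5.0  # clipped to C
        state.g = np.array([5.4])  # step lands at -0.4
        update_multiplier(state, 0, K)
        assert state.alpha[0] == 0.0  # clipped to 0

    def test_invalid_index_rejected(self):
        state = init_state(np.zeros((2, 1)), [1.0, -1.0], C=1.0, epsilon=1e-3)
        with pytest.raises(IndexError):
            update_multiplier(state, 5, np.eye(2))


class TestTrainBinary:
    def test_two_separated_points_match_grid_oracle(self):
        X = np.array([[0.0, 0.0], [10.0, 10.0]])
        t = np.array([1.0, -1.0])
        spec = KernelSpec.gaussian(1.0)
        model = train_binary(X, t, C=5.0, epsilon=1e-3, kernel=spec)
        Q = np.outer(t, t) * gram(X, X, spec)
        assert model.diagnostics["dual_objective"] == pytest.approx(
            qp_oracle_grid(Q, C=5.0), abs=1e-3
        )

    def test_duplicate_point_opposite_labels_hits_bounds(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0]])
        t = np.array([1.0, -1.0])
        spec = KernelSpec.gaussian(1.0)
        model = train_binary(X, t, C=0.5, epsilon=1e-3, kernel=spec)
        # both multipliers pushed to the box bound C
        weights = np.sort(model.weights)
        assert np.allclose(np.abs(weights), 0.5, atol=1e-12)
        Q = np.outer(t, t) * gram(X, X, spec)
        assert model.diagnostics["dual_objective"] == pytest.approx(
            qp_oracle_grid(Q, C=0.5), abs=1e-3
        )

    def test_separable_clouds_reach_perfect_training_accuracy(self, separable_clouds):
        X, t = separable_clouds
        model = train_binary(X, t, C=5.0, kernel=KernelSpec.gaussian(2.0))
        assert np.array_equal(predict_binary(model, X), t)
        assert model.diagnostics["converged"]

    def test_sparsity_on_separable_data(self, separable_clouds):
        X, t = separable_clouds
        model = train_binary(X, t, C=5.0, kernel=KernelSpec.gaussian(2.0))
        assert 0 < model.n_support < len(t)

    def test_stopping_condition_holds_at_exit(self, rng):
        for _ in range(10):
            X, t, C, spec, _ = make_qp(rng, int(rng.integers(2, 5)))
            model = train_binary(X, t, C=C, epsilon=1e-3, kernel=spec)
            if model.diagnostics["converged"]:
                assert model.diagnostics["final_min_J"] > -1e-3

    def test_literal_and_newton_identical_for_gaussian(self, separable_clouds):
        X, t = separable_clouds
        kw = dict(C=5.0, epsilon=1e-3, kernel=KernelSpec.gaussian(2.0))
        lit = train_binary(X, t, mode="literal", **kw)
        newt = train_binary(X, t, mode="newton", **kw)
        assert np.array_equal(lit.weights, newt.weights)
        assert np.array_equal(lit.support_vectors, newt.support_vectors)

    def test_newton_objective_non_increasing(self, rng):
        X, t, C, spec, Q = make_qp(rng, 4)
        state = init_state(X, t, C=C, epsilon=1e-3)
        K = gram(X, X, spec)
        prev = dual_objective_of(state.alpha, Q)
        for _ in range(200):
            c = select_index(state)
            if c is None:
                break
            update_multiplier(state, c, K, mode="newton")
            cur = dual_objective_of(state.alpha, Q)
            assert cur <= prev + 1e-12
            assert np.all((state.alpha >= 0.0) & (state.alpha <= C))
            prev = cur

    def test_label_flip_negates_decision_values(self, separable_clouds):
        X, t = separable_clouds
        kw = dict(C=5.0, epsilon=1e-3, kernel=KernelSpec.gaussian(2.0))
        m_pos = train_binary(X, t, **kw)
        m_neg = train_binary(X, -t, **kw)
        probe = X[:10]
        assert np.allclose(decision_values(m_pos, probe), -decision_values(m_neg, probe), atol=1e-12)

    def test_nonconverged_model_flagged(self, separable_clouds):
        X, t = separable_clouds
        model = train_binary(X, t, max_iter=3, kernel=KernelSpec.gaussian(2.0))
        assert model.diagnostics["converged"] is False
        assert model.diagnostics["iterations"] == 3

    def test_single_class_warns(self, rng):
        with pytest.warns(UserWarning, match="one class"):
            train_binary(rng.normal(size=(3, 2)), [1.0, 1.0, 1.0])


class TestDecisionFunction:
    def test_empty_model_ties_to_positive(self):
        model = BinarySELMModel(
            support_vectors=np.empty((0, 2)),
            weights=np.empty(0),
            kernel=KernelSpec.gaussian(1.0),
        )
        assert decision_value(model, np.zeros(2)) == 0.0
        assert predict_binary(model, np.zeros((1, 2)))[0] == 1.0

    def test_single_support_vector_at_query_point(self):
        x = np.array([1.0, -2.0])
        model = BinarySELMModel(
            support_vectors=x[None, :], weights=np.array([1.0]),
            kernel=KernelSpec.gaussian(500.0),
        )
        assert decision_value(model, x) == pytest.approx(1.0)

    def test_trained_single_sample_reproduces_label(self):
        X = np.array([[3.0, 4.0]])
        model = train_binary(X, [1.0], C=5.0, kernel=KernelSpec.gaussian(500.0))
        assert decision_value(model, X[0]) == pytest.approx(1.0)
        assert predict_binary(model, X)[0] == 1.0

    def test_predictions_ignore_zero_alpha_rows(self, separable_clouds):
        X, t = separable_clouds
        model = train_binary(X, t, C=5.0, kernel=KernelSpec.gaussian(2.0))
        # model retains only alpha > 0 rows; rebuilding from them changes nothing
        rebuilt = BinarySELMModel(
            support_vectors=model.support_vectors.copy(),
            weights=model.weights.copy(),
            kernel=model.kernel,
        )
        assert np.array_equal(decision_values(model, X), decision_values(rebuilt, X))


def test_model_json_round_trip(separable_clouds):
    X, t = separable_clouds
    model = train_binary(X, t, C=5.0, kernel=KernelSpec.gaussian(2.0),
                         positive_label="A", negative_label="D")
    back = model_from_json(model_to_json(model))
    assert np.array_equal(back.support_vectors, model.support_vectors)
    assert np.array_equal(back.weights, model.weights)
    assert back.kernel == model.kernel
    assert back.positive_label == "A" and back.negative_label == "D"
    probe = X[:5]
    assert np.array_equal(decision_values(back, probe), decision_values(model, probe))


def test_random_tiny_instances_match_lbfgsb_oracle(rng):
    worst = 0.0
    for _ in range(30):
        n = int(rng.integers(1, 5))
        X, t, C, spec, Q = make_qp(rng, n)
        model = train_binary(X, t, C=C, epsilon=1e-3, kernel=spec)
        gap = model.diagnostics["dual_objective"] - qp_oracle_lbfgsb(Q, C)
        worst = max(worst, gap)
    assert worst <= 1e-3
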