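import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from conftest import random_cloud
from valvemonitor import (
    InputError,
    ParameterError,
    decision_function,
    predict,
    rbf_kernel,
    score,
    train,
)
from valvemonitor.ocsvm import kernel_matrix

UNIT_SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])


class TestRbfKernel:
    def test_zero_distance_is_one(self, rng):
        x = rng.normal(size=3)
        assert rbf_kernel(x, x, gamma=0.7) == 1.0

    def test_unit_distance_operating_gamma(self):
        assert rbf_kernel((0.0, 0.0), (1.0, 0.0), gamma=7.0) == pytest.approx(
            math.exp(-7.0), rel=1e-12
        )

    def test_symmetry(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=(2, 4))
            assert rbf_kernel(x, y, 2.3) == rbf_kernel(y, x, 2.3)

    def test_range(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=(2, 2))
            k = rbf_kernel(x, y, 1.0)
            assert 0.0 < k <= 1.0

    def test_dimension_mismatch(self):
        with pytest.raises(InputError):
            rbf_kernel([0.0, 1.0], [0.0, 1.0, 2.0], 1.0)

    def test_nonpositive_gamma(self):
        with pytest.raises(ParameterError):
            rbf_kernel([0.0], [1.0], 0.0)

    def test_matrix_agrees_with_scalar(self, rng):
        X = rng.normal(size=(5, 2))
        Y = rng.normal(size=(3, 2))
        K = kernel_matrix(X, Y, 1.7)
        for i in range(5):
            for j in range(3):
                assert K[i, j] == pytest.approx(rbf_kernel(X[i], Y[j], 1.7), rel=1e-12)


class TestTrainConstraints:
    def test_unit_square_matches_qp_oracle(self):
        model = train(UNIT_SQUARE, nu=0.5, gamma=1.0, tol=1e-10)
        alpha_oracle, obj_oracle = oracles.qp_dual_solution(UNIT_SQUARE, nu=0.5, gamma=1.0)
        assert model.dual_objective == pytest.approx(obj_oracle, abs=1e-6)
        # recover the full alpha vector from the support vectors
        full = np.zeros(4)
        for sv, a in zip(model.support_vectors, model.alphas):
            idx = int(np.argmin(np.linalg.norm(UNIT_SQUARE - sv, axis=1)))
            full[idx] = a
        np.testing.assert_allclose(full, alpha_oracle, atol=1e-6)

    def test_constraint_satisfaction(self, rng):
        X = random_cloud(rng, 40)
        model = train(X, nu=0.2, gamma=1.5)
        C = 1.0 / (0.2 * 40)
        assert np.all(model.alphas > 0)
        assert np.all(model.alphas <= C + 1e-12)
        assert np.sum(model.alphas) == pytest.approx(1.0, abs=1e-8)

    def test_infeasible_nu(self):
        with pytest.raises(ParameterError, match="infeasible"):
            train(np.zeros((3, 2)), nu=0.1, gamma=1.0)

    @pytest.mark.parametrize("nu", [0.0, -0.1, 1.5])
    def test_invalid_nu(self, nu):
        with pytest.raises(ParameterError, match="nu"):
            train(UNIT_SQUARE, nu=nu, gamma=1.0)

    def test_invalid_gamma(self):
        with pytest.raises(ParameterError, match="gamma"):
            train(UNIT_SQUARE, nu=0.5, gamma=-1.0)

    def test_empty_features(self):
        with pytest.raises(InputError):
            train(np.zeros((0, 2)), nu=0.5, gamma=1.0)


class TestDecisionFunction:
    def test_margin_support_vector_sits_on_boundary(self, rng):
        X = random_cloud(rng, 50)
        model = train(X, nu=0.3, gamma=0.8, tol=1e-10)
        C = 1.0 / (0.3 * 50)
        margin = (model.alphas > 1e-5 * C) & (model.alphas < C * (1 - 1e-5))
        assert margin.sum() > 0
        values = decision_function(model, model.support_vectors[margin])
        assert np.max(np.abs(values)) < 1e-6

    def test_distant_probe_approaches_minus_rho(self, rng):
        X = random_cloud(rng, 30)
        model = train(X, nu=0.2, gamma=1.0)
        far = np.array([1e4, -1e4])
        assert decision_function(model, far) == pytest.approx(-model.rho, abs=1e-12)
        assert model.rho > 0
        assert predict(model, far) == -1

    def test_batch_equals_per_row(self, rng):
        X = random_cloud(rng, 30)
        model = train(X, nu=0.2, gamma=1.0)
        probes = rng.normal(size=(20, 2))
        batch = decision_function(model, probes)
        singles = np.array([decision_function(model, p) for p in probes])
        np.testing.assert_allclose(batch, singles, rtol=0, atol=1e-12)

    def test_dimension_mismatch(self, rng):
        model = train(random_cloud(rng, 20), nu=0.2, gamma=1.0)
        with pytest.raises(InputError, match="dimension"):
            decision_function(model, np.zeros(3))


class TestPredictAndScore:
    def test_tie_rule_zero_is_inlier(self, rng):
        X = random_cloud(rng, 40)
        model = train(X, nu=0.25, gamma=1.0, tol=1e-10)
        # margin SVs sit on the boundary up to roundoff; the tie rule must
        # classify every one of them as inlier
        C = 1.0 / (0.25 * 40)
        margin = (model.alphas > 1e-5 * C) & (model.alphas < C * (1 - 1e-5))
        assert margin.sum() > 0
        assert np.all(predict(model, model.support_vectors[margin]) == 1)
        values = decision_function(model, X)
        labels = predict(model, X)
        assert np.all((values >= -1e-9) == (labels == 1))

    def test_nu_bounds_training_outliers(self, rng):
        X = random_cloud(rng, 60)
        nu = 0.05
        model = train(X, nu=nu, gamma=1.0)
        outlier_fraction = np.mean(predict(model, X) == -1)
        assert outlier_fraction <= nu + 2.0 / 60

    def test_score_on_distant_probes_is_zero(self, rng):
        X = random_cloud(rng, 30)
        model = train(X, nu=0.2, gamma=1.0)
        probes = X + 1000.0
        assert score(model, probes) == 0.0

    def test_score_empty_raises(self, rng):
        model = train(random_cloud(rng, 20), nu=0.2, gamma=1.0)
        with pytest.raises(InputError):
            score(model, np.zeros((0, 2)))

    def test_training_score_reported(self, rng):
        X = random_cloud(rng, 50)
        model = train(X, nu=0.1, gamma=1.0)
        assert model.training_score == pytest.approx(score(model, X))


class TestProperties:
    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=15, deadline=None)
    def test_oracle_equivalence_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        l = int(rng.integers(10, 40))
        nu = float(rng.choice([0.1, 0.5]))
        gamma = float(rng.choice([0.5, 5.0]))
        X = random_cloud(rng, l)
        model = train(X, nu=nu, gamma=gamma, tol=1e-10)
        _, obj_oracle = oracles.qp_dual_solution(X, nu=nu, gamma=gamma)
        assert model.dual_objective == pytest.approx(obj_oracle, abs=1e-6)

    def test_permutation_invariance(self, rng):
        X = random_cloud(rng, 40)
        probes = rng.normal(size=(30, 2))
        model_a = train(X, nu=0.2, gamma=1.0, tol=1e-10)
        model_b = train(X[rng.permutation(40)], nu=0.2, gamma=1.0, tol=1e-10)
        np.testing.assert_array_equal(
            predict(model_a, probes), predict(model_b, probes)
        )

    def test_gamma_trends(self, rng):
        X = random_cloud(rng, 80)
        lo, hi = np.min(X, axis=0) - 2, np.max(X, axis=0) + 2
        gx, gy = np.meshgrid(np.linspace(lo[0], hi[0], 30), np.linspace(lo[1], hi[1], 30))
        grid = np.column_stack([gx.ravel(), gy.ravel()])
        scores, areas = [], []
        for gamma in (0.1, 1.0, 10.0, 100.0):
            model = train(X, nu=0.1, gamma=gamma)
            scores.append(model.training_score)
            areas.append(np.mean(predict(model, grid) == 1))
        # the inlier area of the probe grid shrinks as gamma grows (the
        # boundary hugs the training points ever more tightly) ...
        assert areas[-1] < areas[0]
        assert all(b <= a + 0.02 for a, b in zip(areas, areas[1:]))
        # ... while the training score stays in the nu-property band: the
        # equality constraint pins the outlier budget, so the score cannot
        # drift far below 1 - nu at any gamma
        assert all(s >= 1.0 - 0.1 - 2.0 / 80 for s in scores[:2])

    def test_small_gamma_flattens_decision_values(self, rng):
        X = random_cloud(rng, 40)
        probes = rng.normal(size=(50, 2))
        spreads = []
        for gamma in (1e-2, 1e-4, 1e-6):
            model = train(X, nu=0.2, gamma=gamma, tol=1e-10)
            spreads.append(np.ptp(decision_function(model, probes)))
        # decision values converge to a common offset as gamma -> 0
        # (spread scales ~linearly with gamma in the flat-kernel limit)
        assert spreads[2] < spreads[1] < spreads[0]
        assert spreads[2] < 0.01 * spreads[0]
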