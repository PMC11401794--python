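import warnings

import numpy as np
import pytest

from convexgsca.als_estimation import (
    ParameterSet,
    fit_cvx,
    fit_std,
    objective_value,
    prepare_moments,
    rescale_weights_unstandardized,
    update_structural_params,
    update_weight_vector,
)
from convexgsca.model_spec import ModelSpec, validate_spec
from convexgsca.moments_io import MomentSet, build_penalty_matrix, moments_from_data

from conftest import random_model


def _two_block_setup():
    """Two convex 3-indicator blocks, g1 -> g2, diagonal covariance with SDs
    [1,2,3] and [100,200,300]."""
    spec = validate_spec(
        ModelSpec({"g1": ["a1", "a2", "a3"], "g2": ["b1", "b2", "b3"]}, {}, [("g1", "g2")])
    )
    sd = np.array([1.0, 2, 3, 100, 200, 300])
    mom = MomentSet(tuple(spec.indicator_names), np.arange(6.0), np.diag(sd**2), 100)
    return spec, mom


class TestObjective:
    def test_null_model_block_contributions(self):
        # with A = 0 and intercepts at the means, each block's indicators
        # contribute sum(sd^2)/avg_sd^2 = 3.5; the dependent component adds
        # its own variance over the block-average SD squared
        spec, mom = _two_block_setup()
        O = build_penalty_matrix(spec, mom)
        W = np.zeros((6, 2))
        W[:3, 0] = W[3:, 1] = 1 / 3
        a0 = np.concatenate([mom.mu, W.T @ mom.mu])
        params = ParameterSet(spec, W, np.zeros((2, 6)), np.zeros((2, 2)), a0)
        f = objective_value(params, mom, O)
        gamma2_var = W[:, 1] @ mom.S @ W[:, 1]
        expected = 3.5 + 3.5 + gamma2_var / 200**2
        assert abs(f - expected) < 1e-12

    def test_zero_residual_is_zero(self):
        # single indicator forming its component: loading 1, intercepts exact
        spec = validate_spec(ModelSpec({"g": ["z1"]}))
        mom = MomentSet(("z1",), np.array([2.0]), np.array([[4.0]]), 20)
        O = build_penalty_matrix(spec, mom)
        params = ParameterSet(spec, np.ones((1, 1)), np.ones((1, 1)), np.zeros((1, 1)),
                              np.zeros(2))
        assert objective_value(params, mom, O) < 1e-12

    def test_moment_form_equals_raw_data_sum_of_squares(self):
        # the expectation form equals SS(raw residuals)/(N-1) on any sample,
        # for any parameter values with intercepts absorbing the means
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 2)) @ np.array([[1.0, 0.4], [0.0, 1.0]]) + [1.0, -2.0]
        spec = validate_spec(ModelSpec({"g": ["z1", "z2"]}))
        mom = moments_from_data(X)
        O = build_penalty_matrix(spec, mom)
        W = np.array([[0.3], [0.7]])
        C = np.array([[0.9, 1.1]])
        M = np.hstack([np.eye(2), W]) - W @ np.hstack([C, np.zeros((1, 1))])
        a0 = M.T @ mom.mu
        params = ParameterSet(spec, W, C, np.zeros((1, 1)), a0)
        f = objective_value(params, mom, O)
        U = np.hstack([X, X @ W])
        resid = (U - a0 - (X @ W) @ np.hstack([C, np.zeros((1, 1))])) * O.o
        assert abs(f - (resid**2).sum() / 39) < 1e-10


class TestConditionalUpdates:
    def test_structural_update_matches_simple_regression(self):
        # one predictor component, outcomes regressed on it: slope =
        # cov/var, intercept = mean equation
        rng = np.random.default_rng(4)
        spec, mom = random_model(rng, allow_standardized=False, max_components=2)
        spec_prep = prepare_moments(spec, mom)
        O = build_penalty_matrix(spec, spec_prep)
        W = np.zeros((spec.J, spec.P))
        for p, comp in enumerate(spec.component_names):
            idx = spec.block_indices(comp)
            W[idx, p] = 1 / len(idx)
        A, a0 = update_structural_params(W, spec_prep, O, spec)
        S, mu = spec_prep.S, spec_prep.mu
        for j in range(spec.J):
            p = int(np.flatnonzero(spec.block_membership()[j])[0])
            gam = W[:, p]
            slope = (gam @ S[:, j]) / (gam @ S @ gam)
            assert abs(A[p, j] - slope) < 1e-10
            assert abs(a0[j] - (mu[j] - slope * (gam @ mu))) < 1e-10

    def test_null_pattern_gives_mean_intercepts(self):
        spec = validate_spec(ModelSpec({"g": ["z1", "z2"]}))
        rng = np.random.default_rng(5)
        _, mom = random_model(rng, max_components=2)
        mom = MomentSet(("z1", "z2"), mom.mu[:2], mom.S[:2, :2], 50)
        W = np.array([[0.5], [0.5]])
        # force A to zero by masking: no edges and pretend no loadings by
        # checking the intercept identity on the component row only
        O = build_penalty_matrix(spec, mom)
        A, a0 = update_structural_params(W, mom, O, spec)
        assert abs(a0[2] - W[:, 0] @ mom.mu) < 1e-12  # b0 = W'mu for exogenous

    def test_single_indicator_weight_fixed(self):
        spec = validate_spec(ModelSpec({"g1": ["z1"], "g2": ["z2", "z3"]}, {}, [("g1", "g2")]))
        rng = np.random.default_rng(6)
        A = rng.standard_normal((3, 5))
        S = A @ A.T / 5 + 0.3 * np.eye(3)
        mom = MomentSet(("z1", "z2", "z3"), np.zeros(3), S, 40)
        fit = fit_cvx(spec, mom, compute_indexes=False)
        assert fit.params.W[0, 0] == 1.0

    def test_exchangeable_indicators_get_equal_weights(self):
        # equal variances, symmetric roles -> (.5, .5)
        spec = validate_spec(ModelSpec({"g": ["z1", "z2"]}))
        S = np.array([[1.0, 0.4], [0.4, 1.0]])
        mom = MomentSet(("z1", "z2"), np.array([1.0, 1.0]), S, 60)
        fit = fit_cvx(spec, mom, compute_indexes=False)
        assert np.allclose(fit.params.W[:, 0], [0.5, 0.5], atol=1e-10)

    def test_weight_update_beats_simplex_grid(self):
        # exact constrained solve vs a dense grid over the 2-simplex,
        # judged by the full profile objective (intercepts optimal per point)
        rng = np.random.default_rng(7)
        spec = validate_spec(ModelSpec({"g1": ["a1", "a2", "a3"], "g2": ["b1", "b2"]}, {}, [("g1", "g2")]))
        A_ = rng.standard_normal((5, 8))
        S = A_ @ A_.T / 8 + 0.4 * np.eye(5)
        mom = MomentSet(tuple(spec.indicator_names), rng.uniform(0, 5, 5), S, 80)
        fit = fit_cvx(spec, mom, compute_indexes=False, tol=1e-10)
        O = fit.penalty
        w_star = fit.params.W[:3, 0]

        def profile_objective(w):
            W = fit.params.W.copy()
            W[:3, 0] = w
            A, a0 = update_structural_params(W, fit.moments, O, spec)
            params = ParameterSet(spec, W, A[:, :5], A[:, 5:], a0)
            return objective_value(params, fit.moments, O)

        def grid_argmin(lo, hi, step, nonneg):
            grid = np.arange(lo, hi + step / 2, step)
            best_f, best_w = np.inf, None
            for w1 in grid:
                for w2 in grid:
                    w3 = 1.0 - w1 - w2
                    if nonneg and (w3 < -1e-12 or w1 < 0 or w2 < 0):
                        continue
                    f = profile_objective(np.array([w1, w2, w3]))
                    if f < best_f:
                        best_f, best_w = f, np.array([w1, w2, w3])
            return best_f, best_w

        # sum-to-one only: the grid must cover negative weights
        f_star = profile_objective(w_star)
        best_f, best_w = grid_argmin(-0.5, 1.5, 0.01, nonneg=False)
        assert f_star <= best_f + 1e-10
        assert np.max(np.abs(w_star - best_w)) <= 0.01

        # with the non-negativity flag: exact simplex solution vs simplex grid
        spec.nonneg_weights = True
        fit_nn = fit_cvx(spec, mom, compute_indexes=False, tol=1e-10)
        w_nn = fit_nn.params.W[:3, 0]
        spec.nonneg_weights = False
        best_f_nn, best_w_nn = grid_argmin(0.0, 1.0, 0.005, nonneg=True)
        assert np.all(w_nn >= -1e-12)
        assert np.max(np.abs(w_nn - best_w_nn)) <= 0.005 + 1e-9


class TestFullFit:
    def test_trace_monotone_on_random_models(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            spec, mom = random_model(rng)
            fit = fit_cvx(spec, mom, compute_indexes=False)
            tr = np.array(fit.objective_trace)
            assert np.all(np.diff(tr) <= 1e-12 * np.maximum(tr[:-1], 1.0))

    def test_partial_scale_invariance(self):
        # per-block positive affine rescaling: identical weights and minimum
        rng = np.random.default_rng(9)
        spec, mom = random_model(rng, allow_standardized=False)
        fit1 = fit_cvx(spec, mom, compute_indexes=False, tol=1e-12)
        scale = np.ones(spec.J)
        shift = np.zeros(spec.J)
        for k, comp in enumerate(spec.component_names):
            idx = spec.block_indices(comp)
            scale[idx] = [0.1, 10.0, 3.0][k % 3]
            shift[idx] = [3.0, -5.0, 0.0][k % 3]
        mom2 = MomentSet(mom.names, scale * mom.mu + shift,
                         mom.S * np.outer(scale, scale), mom.N)
        fit2 = fit_cvx(spec, mom2, compute_indexes=False, tol=1e-12)
        assert np.allclose(fit1.params.W, fit2.params.W, atol=1e-8)
        assert abs(fit1.objective - fit2.objective) < 1e-8 * max(fit1.objective, 1.0)

    def test_all_standardized_reduces_to_classic_fit(self):
        rng = np.random.default_rng(10)
        spec, mom = random_model(rng)
        std_spec = validate_spec(
            ModelSpec(spec.blocks, {c: "standardized" for c in spec.component_names},
                      spec.structural_edges)
        )
        f1 = fit_cvx(std_spec, mom, compute_indexes=False, tol=1e-12)
        f2 = fit_std(spec, mom, compute_indexes=False, tol=1e-12)
        assert np.allclose(f1.params.W, f2.params.W, atol=1e-8)
        assert np.allclose(f1.params.A, f2.params.A, atol=1e-8)

    def test_moment_sufficiency(self):
        rng = np.random.default_rng(12)
        spec, mom = random_model(rng, allow_standardized=False, max_components=2)
        X = rng.multivariate_normal(mom.mu, mom.S, size=150)
        f_raw = fit_cvx(spec, X, compute_indexes=False)
        f_mom = fit_cvx(spec, moments_from_data(X), compute_indexes=False)
        assert np.allclose(f_raw.params.W, f_mom.params.W, atol=1e-10)
        assert np.allclose(f_raw.params.a0, f_mom.params.a0, atol=1e-10)

    def test_nonneg_constraint_respected(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            spec, mom = random_model(rng, allow_standardized=False)
            spec.nonneg_weights = True
            fit = fit_cvx(spec, mom, compute_indexes=False)
            for p, comp in enumerate(spec.component_names):
                idx = spec.block_indices(comp)
                w = fit.params.W[idx, p]
                assert np.all(w >= -1e-12)
                assert abs(w.sum() - 1.0) < 1e-10
            tr = np.array(fit.objective_trace)
            assert np.all(np.diff(tr) <= 1e-12 * np.maximum(tr[:-1], 1.0))

    def test_convex_sum_to_one_every_solution(self):
        rng = np.random.default_rng(14)
        spec, mom = random_model(rng)
        fit = fit_cvx(spec, mom, compute_indexes=False, n_starts=3, seed=0)
        for p, comp in enumerate(spec.component_names):
            idx = spec.block_indices(comp)
            w = fit.params.W[idx, p]
            if spec.scale_of(comp) == "convex":
                assert abs(w.sum() - 1.0) < 1e-10
            else:
                Sb = fit.moments.S[np.ix_(idx, idx)]
                assert abs(w @ Sb @ w - 1.0) < 1e-8

    def test_degenerate_convex_block_rejected(self):
        spec = validate_spec(ModelSpec({"g": ["z1", "z2"]}))
        S = np.array([[1.0, 1.0], [1.0, 1.0]])
        mom = MomentSet(("z1", "z2"), np.zeros(2), S, 30)
        with pytest.raises(ValueError, match="linearly dependent"):
            fit_cvx(spec, mom)


class TestStandardizedComparator:
    def test_intro_toy_exact(self):
        # two intelligence tests {49,50,51} and {0,50,100}: standardized
        # weights are (.5, .5); the ad-hoc rescaling yields (.5, .01)
        import pandas as pd

        X = pd.DataFrame(
            [[49.0, 0.0], [50.0, 50.0], [51.0, 100.0]], columns=["t1", "t2"]
        )
        spec = validate_spec(ModelSpec({"intel": ["t1", "t2"]}))
        mom = moments_from_data(X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # perfectly correlated pair -> ridge direction
            fit = fit_std(spec, mom, compute_indexes=False)
        assert np.allclose(fit.params.W[:, 0], [0.5, 0.5], atol=1e-10)
        W_uni, means = rescale_weights_unstandardized(fit, mom)
        assert np.allclose(W_uni[:, 0], [0.5, 0.01], atol=1e-12)
        assert abs(means[0] - (0.5 * 50 + 0.01 * 50)) < 1e-8

    def test_unit_sd_rescale_is_identity(self):
        rng = np.random.default_rng(15)
        spec, mom = random_model(rng, allow_standardized=False, max_components=2)
        R = mom.correlation()
        mom_unit = MomentSet(mom.names, np.zeros(mom.J), R, mom.N)
        fit = fit_std(spec, mom_unit, compute_indexes=False)
        W_uni, _ = rescale_weights_unstandardized(fit, mom_unit)
        assert np.allclose(W_uni, fit.params.W, atol=1e-12)
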