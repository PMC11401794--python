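import numpy as np
import pytest
from scipy import stats

from convexgsca.als_estimation import fit_cvx
from convexgsca.moments_io import moments_from_data
from convexgsca.simulation import (
    TABLE_CORRELATION_CONDITIONS,
    VARIANCE_CONDITIONS,
    PopulationModel,
    build_population_moments,
    default_population,
    draw_sample,
    fleishman_coefficients,
    population_parameters,
    run_recovery_study,
)


class TestPopulationMoments:
    def test_unit_variance_blocks_reproduce_correlation_pattern(self):
        pop = default_population(corr_condition=1, variance_condition=1, component_corr=0.0)
        m = build_population_moments(pop)
        # first block, unit SDs: covariance equals the printed correlations
        assert m.S[0, 1] == pytest.approx(0.24, abs=1e-12)
        assert np.allclose(m.S[:4, :4], TABLE_CORRELATION_CONDITIONS[1])

    def test_zero_component_correlation_gives_zero_cross_blocks(self):
        pop = default_population(component_corr=0.0)
        m = build_population_moments(pop)
        assert np.allclose(m.S[:4, 4:], 0.0)

    def test_block_covariance_matches_drd_oracle(self):
        pop = default_population(corr_condition=2, variance_condition=3)
        m = build_population_moments(pop)
        d = np.sqrt(VARIANCE_CONDITIONS[3])
        oracle = np.diag(d) @ TABLE_CORRELATION_CONDITIONS[2] @ np.diag(d)
        assert np.allclose(m.S[:4, :4], oracle, atol=1e-12)

    def test_component_covariance_reproduced_by_seed_weights(self):
        pop = default_population(component_corr=0.4)
        m = build_population_moments(pop)
        spec = pop.spec
        W = np.zeros((spec.J, spec.P))
        phi = np.zeros(spec.P)
        for p, c in enumerate(spec.component_names):
            idx = spec.block_indices(c)
            W[idx, p] = pop.seed_weight(c)
            phi[p] = W[idx, p] @ m.S[np.ix_(idx, idx)] @ W[idx, p]
        G = W.T @ m.S @ W
        R = G / np.outer(np.sqrt(phi), np.sqrt(phi))
        off = R[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.4, atol=1e-10)

    def test_infeasible_prescription_raises(self):
        pop = default_population(component_corr=0.999)
        pop.within_block_corr = {c: np.eye(4) * 1.0 for c in pop.spec.component_names}
        # near-unit component correlations with weakly correlated indicators
        # cannot come from any PSD covariance
        with pytest.raises(ValueError):
            build_population_moments(pop)

    def test_structural_paths_enter_component_covariance(self):
        from convexgsca.model_spec import ModelSpec, validate_spec

        spec = validate_spec(
            ModelSpec(
                {"g1": ["z1", "z2"], "g2": ["z3", "z4"]},
                {},
                [("g1", "g2")],
            )
        )
        pop = PopulationModel(
            spec=spec,
            block_means={"g1": np.zeros(2), "g2": np.zeros(2)},
            block_sds={"g1": np.ones(2), "g2": np.ones(2)},
            within_block_corr={c: np.array([[1.0, 0.5], [0.5, 1.0]]) for c in ("g1", "g2")},
            paths={("g1", "g2"): 0.6},
        )
        m = build_population_moments(pop)
        W = np.zeros((4, 2))
        W[:2, 0] = W[2:, 1] = 0.5
        G = W.T @ m.S @ W
        assert G[0, 1] == pytest.approx(0.6 * G[0, 0], abs=1e-10)
        # an impossible path magnitude exhausts the outcome variance
        pop.paths[("g1", "g2")] = 5.0
        with pytest.raises(ValueError, match="residual variance"):
            build_population_moments(pop)


def test_exact_moment_fit_recovers_population_parameters():
    # fitting the exact population moments reproduces the population
    # parameter values (identifiability at the population level)
    pop = default_population()
    m = build_population_moments(pop)
    truth = population_parameters(pop, m)
    refit = fit_cvx(pop.spec, m, tol=1e-12, max_iter=5000, compute_indexes=False)
    assert np.allclose(refit.params.W, truth.params.W, atol=1e-6)
    assert np.allclose(refit.params.C, truth.params.C, atol=1e-6)
    assert np.allclose(refit.params.B, truth.params.B, atol=1e-6)


class TestSampling:
    def test_seeded_draws_are_identical(self):
        m = build_population_moments(default_population())
        a = draw_sample(m, 50, seed=5)
        b = draw_sample(m, 50, seed=5)
        assert a.equals(b)

    def test_normal_margins(self):
        m = build_population_moments(default_population(variance_condition=1))
        X = draw_sample(m, 200_000, seed=6).to_numpy()
        assert np.max(np.abs(stats.skew(X, axis=0))) < 0.03
        assert np.max(np.abs(stats.kurtosis(X, axis=0))) < 0.08
        assert np.max(np.abs(X.mean(axis=0) - m.mu)) < 0.02

    def test_fleishman_coefficient_moments(self):
        # verify the polynomial's moments directly by Gauss-Hermite quadrature
        a, b, c, d = fleishman_coefficients(1.25, 3.75)
        xs, ws = np.polynomial.hermite_e.hermegauss(40)
        ws = ws / ws.sum()
        y = a + b * xs + c * xs**2 + d * xs**3
        m1 = ws @ y
        m2 = ws @ (y - m1) ** 2
        m3 = ws @ (y - m1) ** 3
        m4 = ws @ (y - m1) ** 4
        assert m1 == pytest.approx(0.0, abs=1e-10)
        assert m2 == pytest.approx(1.0, abs=1e-10)
        assert m3 / m2**1.5 == pytest.approx(1.25, abs=1e-8)
        assert m4 / m2**2 - 3 == pytest.approx(3.75, abs=1e-7)

    def test_nonnormal_margins_and_covariance(self):
        m = build_population_moments(default_population())
        X = draw_sample(m, 200_000, marginal=(1.25, 3.75), seed=7).to_numpy()
        sk = stats.skew(X, axis=0)
        ku = stats.kurtosis(X, axis=0)
        assert np.max(np.abs(sk - 1.25)) < 0.05
        # the sample-kurtosis estimator of this margin has SD ~ 0.17 at this
        # N, so bound the across-margin mean tightly and the max loosely
        assert abs(ku.mean() - 3.75) < 0.15
        assert np.max(np.abs(ku - 3.75)) < 0.7
        # intermediate-correlation adjustment preserves the covariance target
        err = np.abs(np.corrcoef(X, rowvar=False) - m.correlation())
        assert err.max() < 0.01

    def test_infeasible_shape_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            fleishman_coefficients(3.0, 1.0)


class TestRecovery:
    def test_hand_checked_bias_rmse_arithmetic(self):
        # replicates {1.1, 0.9} around truth 1: bias 0, RMSE 0.1 — checked
        # through the same aggregation used by the study table
        est = np.array([1.1, 0.9])
        bias = abs(est.mean() - 1.0)
        rmse = np.sqrt(((est - 1.0) ** 2).mean())
        assert bias == pytest.approx(0.0, abs=1e-15)
        assert rmse == pytest.approx(0.1, abs=1e-12)

    def test_small_study_structure_and_jensen(self):
        pop = default_population()
        rep = run_recovery_study(pop, N_list=(100, 400), reps=8, seed=8)
        assert set(rep.table["family"]) == {
            "weight", "loading", "intercept", "component_mean", "component_variance"
        }
        # RMSE >= |bias| per parameter (Jensen)
        assert (rep.detail["rmse"] >= rep.detail["abs_bias"] - 1e-12).all()
        assert rep.n_failed == 0
        # weight error shrinks with N
        w = rep.table[rep.table.family == "weight"].sort_values("N")
        assert w.rmse.iloc[-1] < w.rmse.iloc[0]
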