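"""Linear predictor, logistic probability, likelihood, MCMC and stepwise selection."""

import numpy as np
import pytest

from stoclcc.covariates import CovariateStack
from stoclcc.grids import DEFORESTED, FOREST, REGEN
from stoclcc.model import (
    ChainConfig,
    DegenerateSplitError,
    PredictorSpec,
    TransitionKind,
    calibration_data,
    fit_mcmc,
    forward_stepwise,
    kappa,
    log_likelihood,
    transition_probability,
)

from conftest import grid_from_codes


def make_stack(n=100, seed=0, **layers):
    """1 x n stack with given (or random) layers, all cells valid."""
    rng = np.random.default_rng(seed)
    base = {
        name: rng.random((1, n)) for name in
        ("dist_roads", "dist_rivers", "dist_settlements", "protected",
         "contagion_defor", "contagion_regen", "palu", "arf", "fc")
    }
    for name, vals in layers.items():
        base[name] = np.asarray(vals, dtype=float).reshape(1, n)
    return CovariateStack(2000, base, np.ones((1, n), dtype=bool))


class TestPredictorSpec:
    def test_history_metrics_only_for_regen_to_deforested(self):
        PredictorSpec(TransitionKind.RtoD, ("arf", "fc"))
        with pytest.raises(ValueError, match="RtoD only"):
            PredictorSpec(TransitionKind.FtoD, ("palu",))

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            PredictorSpec(TransitionKind.FtoD, ("protected", "protected"))


class TestKappa:
    def test_zero_coefficients_give_zero(self):
        stack = make_stack(10)
        spec = PredictorSpec(TransitionKind.FtoD, ("dist_roads",))
        out = kappa(spec, np.zeros(2), stack, np.arange(10))
        np.testing.assert_array_equal(out, 0.0)

    def test_intercept_only(self):
        stack = make_stack(10)
        spec = PredictorSpec(TransitionKind.FtoD, ())
        np.testing.assert_allclose(kappa(spec, [-2.0], stack, np.arange(10)), -2.0)

    def test_intercept_plus_contagion(self):
        # intercept -2, contagion coefficient 4, contagion 0.5 => kappa 0
        stack = make_stack(4, contagion_defor=[0.5, 0.5, 0.5, 0.5])
        spec = PredictorSpec(TransitionKind.FtoD, ("contagion_defor",))
        np.testing.assert_allclose(
            kappa(spec, [-2.0, 4.0], stack, np.arange(4)), 0.0, atol=1e-12
        )

    def test_linear_in_each_coefficient(self):
        stack = make_stack(20, seed=3)
        spec = PredictorSpec(TransitionKind.FtoD, ("dist_roads", "protected"))
        cells = np.arange(20)
        b = np.array([0.5, -1.0, 2.0])
        k0 = kappa(spec, b, stack, cells)
        for j in range(3):
            db = np.zeros(3)
            db[j] = 0.7
            k1 = kappa(spec, b + db, stack, cells)
            col = np.ones(20) if j == 0 else stack.layer(spec.covariate_names[j - 1]).ravel()[cells]
            np.testing.assert_allclose(k1 - k0, 0.7 * col)

    def test_wrong_coefficient_count_raises(self):
        stack = make_stack(5)
        spec = PredictorSpec(TransitionKind.FtoD, ("dist_roads",))
        with pytest.raises(ValueError, match="coefficients"):
            kappa(spec, [1.0], stack, np.arange(5))


class TestTransitionProbability:
    def test_midpoint_and_asymptotes(self):
        assert transition_probability(0.0) == pytest.approx(0.5)
        assert transition_probability(-1e3) == pytest.approx(0.0, abs=1e-12)
        assert transition_probability(1e3) == pytest.approx(1.0)

    def test_log3_maps_to_three_quarters(self):
        assert transition_probability(np.log(3.0)) == pytest.approx(0.75)

    def test_strictly_increasing(self):
        ks = np.linspace(-8, 8, 200)
        assert np.all(np.diff(transition_probability(ks)) > 0)


class TestLogLikelihood:
    def test_single_cell_half(self):
        assert log_likelihood(np.array([1]), np.array([0.5])) == pytest.approx(
            -0.693147, abs=1e-6
        )

    def test_perfect_prediction_limit(self):
        eps = 1e-9
        ll = log_likelihood(np.array([1, 0]), np.array([1 - eps, eps]))
        assert ll == pytest.approx(0.0, abs=1e-8)

    def test_matches_per_cell_loop(self):
        rng = np.random.default_rng(8)
        Z = rng.integers(0, 2, 20)
        P = rng.uniform(0.01, 0.99, 20)
        brute = sum(
            np.log(p) if z == 1 else np.log(1 - p) for z, p in zip(Z, P)
        )
        assert log_likelihood(Z, P) == pytest.approx(brute, abs=1e-10)

    def test_saturated_prediction_is_optimal(self):
        rng = np.random.default_rng(9)
        Z = rng.integers(0, 2, 30)
        saturated = log_likelihood(Z, Z.astype(float))
        for _ in range(50):
            other = rng.uniform(0, 1, 30)
            assert saturated >= log_likelihood(Z, other)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="lengths"):
            log_likelihood(np.array([1, 0]), np.array([0.5]))


def test_calibration_data_excludes_third_class_moves():
    start = grid_from_codes(
        [[FOREST, FOREST, FOREST, REGEN]], year=2000
    )
    end = grid_from_codes(
        [[DEFORESTED, FOREST, REGEN, DEFORESTED]], year=2001
    )
    cells, Z = calibration_data(start, end, TransitionKind.FtoD)
    # forest cell that became regeneration (third class) is excluded
    assert cells.tolist() == [0, 1]
    assert Z.tolist() == [1, 0]


class TestFitMCMC:
    def test_intercept_only_recovers_positive_rate(self):
        rng = np.random.default_rng(1)
        n = 4000
        Z = (rng.random(n) < 0.30).astype(np.int8)
        stack = make_stack(n)
        spec = PredictorSpec(TransitionKind.FtoD, ())
        post = fit_mcmc(spec, Z, stack, np.arange(n),
                        ChainConfig(iterations=3000, n_retain=300, seed=2))
        # closed-form MLE is logit of the sample mean
        mle = np.log(Z.mean() / (1 - Z.mean()))
        assert post.mean[0] == pytest.approx(mle, abs=0.15)
        p_mean = 1 / (1 + np.exp(-post.mean[0]))
        assert p_mean == pytest.approx(Z.mean(), abs=0.03)

    def test_recovers_simulated_slope(self):
        rng = np.random.default_rng(4)
        n = 5000
        contagion = rng.random(n)
        k_true = -1.0 + 3.0 * contagion
        Z = (rng.random(n) < 1 / (1 + np.exp(-k_true))).astype(np.int8)
        stack = make_stack(n, contagion_defor=contagion)
        spec = PredictorSpec(TransitionKind.FtoD, ("contagion_defor",))
        post = fit_mcmc(spec, Z, stack, np.arange(n),
                        ChainConfig(iterations=4000, n_retain=400, seed=5))
        for true_val, (lo, hi) in zip((-1.0, 3.0), post.ci95):
            assert lo <= true_val <= hi

    def test_same_seed_identical_samples(self):
        rng = np.random.default_rng(6)
        Z = (rng.random(500) < 0.2).astype(np.int8)
        stack = make_stack(500)
        spec = PredictorSpec(TransitionKind.FtoD, ("dist_roads",))
        cfg = ChainConfig(iterations=1000, n_retain=200, seed=77)
        p1 = fit_mcmc(spec, Z, stack, np.arange(500), cfg)
        p2 = fit_mcmc(spec, Z, stack, np.arange(500), cfg)
        np.testing.assert_array_equal(p1.samples, p2.samples)

    def test_mean_lies_within_credible_interval(self):
        rng = np.random.default_rng(10)
        Z = (rng.random(800) < 0.4).astype(np.int8)
        stack = make_stack(800)
        spec = PredictorSpec(TransitionKind.FtoD, ("protected",))
        post = fit_mcmc(spec, Z, stack, np.arange(800),
                        ChainConfig(iterations=1500, n_retain=200, seed=3))
        assert np.all(post.ci95[:, 0] <= post.mean)
        assert np.all(post.mean <= post.ci95[:, 1])

    def test_too_few_cells_raises(self):
        stack = make_stack(15)
        spec = PredictorSpec(TransitionKind.FtoD, ("dist_roads",))
        with pytest.raises(ValueError, match="training cells"):
            fit_mcmc(spec, np.ones(15, dtype=np.int8), stack, np.arange(15))


class TestForwardStepwise:
    def _dataset(self, n, seed, active=None):
        rng = np.random.default_rng(seed)
        layers = {
            name: rng.random(n) for name in
            ("contagion_defor", "contagion_regen", "dist_roads",
             "dist_rivers", "dist_settlements")
        }
        k = -1.5 * np.ones(n)
        if active:
            k = k + 4.0 * layers[active]
        Z = (rng.random(n) < 1 / (1 + np.exp(-k))).astype(np.int8)
        stack = make_stack(n, **layers)
        return stack, Z, np.arange(n)

    CANDIDATES = ("contagion_defor", "contagion_regen", "dist_roads",
                  "dist_rivers", "dist_settlements")

    def test_active_covariate_is_selected(self):
        stack, Z, cells = self._dataset(5000, seed=11, active="dist_roads")
        fit = forward_stepwise(
            TransitionKind.FtoD, self.CANDIDATES, stack, Z, cells,
            chain=ChainConfig(iterations=1200, n_retain=200, seed=1), split_seed=1,
        )
        assert "dist_roads" in fit.spec.covariate_names

    def test_inert_covariates_yield_near_intercept_model(self):
        stack, Z, cells = self._dataset(10000, seed=12, active=None)
        fit = forward_stepwise(
            TransitionKind.FtoD, self.CANDIDATES, stack, Z, cells,
            chain=ChainConfig(iterations=1200, n_retain=200, seed=2), split_seed=2,
        )
        assert len(fit.spec.covariate_names) <= 1

    def test_deterministic_given_seeds(self):
        stack, Z, cells = self._dataset(2000, seed=13, active="contagion_defor")
        kw = dict(chain=ChainConfig(iterations=800, n_retain=150, seed=3), split_seed=3)
        f1 = forward_stepwise(TransitionKind.FtoD, self.CANDIDATES, stack, Z, cells, **kw)
        f2 = forward_stepwise(TransitionKind.FtoD, self.CANDIDATES, stack, Z, cells, **kw)
        assert f1.spec == f2.spec
        assert f1.test_ll == f2.test_ll
        np.testing.assert_array_equal(f1.posterior.samples, f2.posterior.samples)

    def test_train_and_test_likelihoods_nonpositive(self):
        stack, Z, cells = self._dataset(2000, seed=14, active="dist_rivers")
        fit = forward_stepwise(
            TransitionKind.FtoD, self.CANDIDATES, stack, Z, cells,
            chain=ChainConfig(iterations=800, n_retain=150, seed=4), split_seed=4,
        )
        assert fit.train_ll <= 0 and fit.test_ll <= 0

    def test_degenerate_split_raises_with_transition_name(self):
        stack = make_stack(200)
        Z = np.zeros(200, dtype=np.int8)
        Z[0] = 1
        with pytest.raises(DegenerateSplitError, match="FtoD"):
            forward_stepwise(
                TransitionKind.FtoD, self.CANDIDATES, stack, Z, np.arange(200),
                chain=ChainConfig(iterations=400, n_retain=100, seed=5), split_seed=5,
            )


def test_sign_conventions_match_expected_driver_effects(recovery_scenario):
    """Deforestation near roads and outside reserves; regeneration far from roads."""
    from stoclcc.covariates import assemble_stack, compute_static_layers
    from stoclcc.synth import DEFAULT_TRUTH, truth_coefficients

    scenario, series = recovery_scenario
    start, end = series.grid_for(2000), series.grid_for(2001)
    static = compute_static_layers(scenario.features, scenario.cell_size)
    stack = assemble_stack(start, series, scenario.features, year=2000, static=static)

    def univariate_mean(kind, cov):
        cells, Z = calibration_data(start, end, kind)
        post = fit_mcmc(PredictorSpec(kind, (cov,)), Z, stack, cells,
                        ChainConfig(iterations=2500, n_retain=250, seed=9))
        return post.mean[1]

    assert univariate_mean(TransitionKind.FtoD, "dist_roads") < 0
    assert univariate_mean(TransitionKind.FtoD, "protected") < 0
    assert univariate_mean(TransitionKind.DtoR, "dist_roads") > 0
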