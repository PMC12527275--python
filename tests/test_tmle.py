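import numpy as np
import pytest
from scipy.special import expit

from dctmle import (
    DGPConfig,
    LearnerSpec,
    OutcomeScale,
    clever_covariates,
    eif_variance,
    fit_fluctuation,
    fit_superlearner,
    generate_dataset,
    local_ate,
    propensity_bound,
    update_predictions,
)
from dctmle.data import scale_outcome
from dctmle.errors import EstimationError, SampleSizeError
from dctmle.tmle import (
    FluctuationFit,
    bound_propensity,
    run_split_tmle,
    _split_tmle_details,
)

from _oracles import irls_fluctuation


class TestPropensityBound:
    def test_closed_form_n5735(self):
        expected = 5.0 / (np.sqrt(5735) * np.log(5735))
        assert propensity_bound(5735) == pytest.approx(expected, rel=1e-12)
        assert propensity_bound(5735) == pytest.approx(0.00763, abs=5e-5)

    def test_closed_form_n100(self):
        assert propensity_bound(100) == pytest.approx(5.0 / (10 * np.log(100)), rel=1e-12)
        assert propensity_bound(100) == pytest.approx(0.1086, abs=5e-4)

    def test_clipping_hits_bound_exactly(self):
        b = propensity_bound(5735)
        clipped = bound_propensity(np.array([0.0, 1.0, 0.5]), b)
        assert clipped[0] == b
        assert clipped[1] == 1.0 - b
        assert clipped[2] == 0.5

    def test_too_small_sample(self):
        with pytest.raises(SampleSizeError):
            propensity_bound(4)

    def test_monotone_bounding(self):
        # widening the bounds never changes values already inside them
        rng = np.random.default_rng(0)
        pi = rng.uniform(0.3, 0.7, 50)
        narrow = bound_propensity(pi, 0.2)
        wide = bound_propensity(pi, 0.05)
        np.testing.assert_array_equal(narrow, wide)


class TestCleverCovariates:
    def test_examples(self):
        h1, h0 = clever_covariates(np.array([1.0]), np.array([0.5]))
        assert h1[0] == pytest.approx(2.0) and h0[0] == 0.0
        h1, h0 = clever_covariates(np.array([0.0]), np.array([0.2]))
        assert h1[0] == 0.0 and h0[0] == pytest.approx(1.25)

    def test_zero_pattern(self):
        rng = np.random.default_rng(1)
        a = rng.binomial(1, 0.5, 100).astype(float)
        pi = rng.uniform(0.1, 0.9, 100)
        h1, h0 = clever_covariates(a, pi)
        assert (h1[a == 0] == 0).all() and (h0[a == 1] == 0).all()

    def test_mean_h1_near_one_under_true_propensity(self):
        rng = np.random.default_rng(2)
        pi = rng.uniform(0.2, 0.8, 20000)
        a = rng.binomial(1, pi)
        h1, _ = clever_covariates(a, pi)
        assert np.mean(h1) == pytest.approx(1.0, abs=0.03)

    def test_unbounded_pi_rejected(self):
        with pytest.raises(ValueError):
            clever_covariates(np.array([1.0]), np.array([0.0]))


class TestFitFluctuation:
    def test_zero_when_offset_already_optimal(self):
        rng = np.random.default_rng(3)
        mu_a = rng.uniform(0.2, 0.8, 50)
        a = rng.binomial(1, 0.5, 50).astype(float)
        h1, h0 = clever_covariates(a, rng.uniform(0.3, 0.7, 50))
        fit = fit_fluctuation(mu_a, h1, h0, mu_a)
        assert fit.eps1 == pytest.approx(0.0, abs=1e-8)
        assert fit.eps0 == pytest.approx(0.0, abs=1e-8)

    def test_matches_irls_oracle_on_toy(self):
        a = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        pi = np.array([0.40, 0.70, 0.55, 0.30, 0.60, 0.45])
        mu_a = np.array([0.30, 0.60, 0.50, 0.40, 0.70, 0.20])
        y_star = np.array([0.35, 0.50, 0.60, 0.30, 0.80, 0.25])
        h1, h0 = clever_covariates(a, pi)
        fit = fit_fluctuation(y_star, h1, h0, mu_a)
        e1, e0 = irls_fluctuation(y_star, h1, h0, mu_a)
        assert fit.eps1 == pytest.approx(e1, abs=1e-6)
        assert fit.eps0 == pytest.approx(e0, abs=1e-6)

    def test_finite_with_tiny_exposure_arm(self):
        rng = np.random.default_rng(4)
        n = 40
        a = np.zeros(n)
        a[:2] = 1.0  # only 2 exposed rows
        pi = rng.uniform(0.2, 0.5, n)
        mu_a = rng.uniform(0.2, 0.8, n)
        y_star = np.clip(mu_a + rng.normal(0, 0.05, n), 0.01, 0.99)
        h1, h0 = clever_covariates(a, pi)
        fit = fit_fluctuation(y_star, h1, h0, mu_a)
        assert np.isfinite(fit.eps1) and np.isfinite(fit.eps0)

    def test_mu_a_on_boundary_rejected(self):
        with pytest.raises(ValueError):
            fit_fluctuation(
                np.array([0.5, 0.5]), np.array([2.0, 0.0]), np.array([0.0, 2.0]), np.array([1.0, 0.5])
            )

    def test_nonfinite_coefficients_rejected(self):
        with pytest.raises(Exception):
            FluctuationFit(np.nan, 0.0)


class TestUpdatePredictions:
    def test_identity_at_zero_epsilon(self):
        rng = np.random.default_rng(5)
        mu1, mu0 = rng.uniform(0.1, 0.9, 30), rng.uniform(0.1, 0.9, 30)
        pi = rng.uniform(0.2, 0.8, 30)
        u1, u0 = update_predictions(mu1, mu0, pi, FluctuationFit(0.0, 0.0))
        np.testing.assert_allclose(u1, mu1)
        np.testing.assert_allclose(u0, mu0)

    def test_closed_form_point(self):
        u1, _ = update_predictions(
            np.array([0.5]), np.array([0.5]), np.array([0.5]), FluctuationFit(0.1, 0.0)
        )
        assert u1[0] == pytest.approx(expit(0.2), abs=1e-12)

    def test_stays_in_unit_interval(self):
        rng = np.random.default_rng(6)
        mu1, mu0 = rng.uniform(0.01, 0.99, 100), rng.uniform(0.01, 0.99, 100)
        pi = rng.uniform(0.2, 0.8, 100)
        u1, u0 = update_predictions(mu1, mu0, pi, FluctuationFit(2.0, -2.0))
        assert ((u1 > 0) & (u1 < 1)).all() and ((u0 > 0) & (u0 < 1)).all()


class TestLocalAte:
    def test_equal_predictions_give_zero(self):
        scale = OutcomeScale(0.0, 10.0, "continuous")
        mu = np.full(20, 0.37)
        assert local_ate(mu, mu, scale) == 0.0

    def test_constant_difference(self):
        scale = OutcomeScale(0.0, 10.0, "continuous")
        assert local_ate(np.full(9, 0.6), np.full(9, 0.4), scale) == pytest.approx(2.0)

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(7)
        scale = OutcomeScale(-2.0, 13.0, "continuous")
        mu1, mu0 = rng.uniform(0, 1, 64), rng.uniform(0, 1, 64)
        brute = np.mean((mu1 * scale.span + scale.y_min) - (mu0 * scale.span + scale.y_min))
        assert local_ate(mu1, mu0, scale) == pytest.approx(brute, abs=1e-12)

    def test_empty_split_rejected(self):
        with pytest.raises(EstimationError):
            local_ate(np.array([]), np.array([]), OutcomeScale(0, 1, "continuous"))


class TestEifVariance:
    def test_formula_instantiation_single_treated_row(self):
        # EIC of an a=1 row is (1/pi)(y - mu1) + mu1 - mu0 - ate
        y = np.array([5.0, 3.0])
        a = np.array([1.0, 0.0])
        pi = np.array([0.5, 0.5])
        mu1, mu0 = np.array([4.0, 2.0]), np.array([1.0, 1.5])
        ate = 1.75
        eic_row0 = (1 / 0.5) * (5.0 - 4.0) + 4.0 - 1.0 - ate
        eic_row1 = -(1 / 0.5) * (3.0 - 1.5) + 2.0 - 1.5 - ate
        expected = np.var([eic_row0, eic_row1], ddof=1) / 2
        assert eif_variance(y, a, pi, mu1, mu0, ate) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_case(self):
        # y equals the observed-arm prediction and the CATE is constant
        y = np.array([2.0, 1.0, 2.0, 1.0])
        a = np.array([1.0, 0.0, 1.0, 0.0])
        pi = np.full(4, 0.5)
        mu1, mu0 = np.full(4, 2.0), np.full(4, 1.0)
        assert eif_variance(y, a, pi, mu1, mu0, 1.0) == 0.0

    def test_scaled_space_oracle(self):
        # computing the EIC in scaled space and multiplying by range^2 is identical
        rng = np.random.default_rng(8)
        n = 50
        scale = OutcomeScale(0.0, 20.0, "continuous")
        y = rng.uniform(0, 20, n)
        a = rng.binomial(1, 0.5, n).astype(float)
        pi = rng.uniform(0.2, 0.8, n)
        m1s, m0s = rng.uniform(0.1, 0.9, n), rng.uniform(0.1, 0.9, n)
        m1, m0 = m1s * scale.span, m0s * scale.span
        ate = float(np.mean(m1 - m0))
        ys = scale_outcome(y, scale)
        eic_star = (a / pi - (1 - a) / (1 - pi)) * (ys - np.where(a == 1, m1s, m0s)) + m1s - m0s - ate / scale.span
        expected = np.var(eic_star * scale.span, ddof=1) / n
        assert eif_variance(y, a, pi, m1, m0, ate) == pytest.approx(expected, rel=1e-10)

    def test_too_few_rows(self):
        with pytest.raises(EstimationError):
            eif_variance(np.array([1.0]), np.array([1.0]), np.array([0.5]), np.array([1.0]), np.array([0.5]), 0.5)


class TestRunSplitTmle:
    def _models(self, dataset, seed=0):
        from dctmle.crossfit import RunSettings, _exposure_design, _outcome_design

        settings = RunSettings(num_cf=1, cv_folds=3, learners_exposure=(LearnerSpec("glm"),), seed=seed)
        scale = dataset.outcome_scale()
        exposure = fit_superlearner(
            _exposure_design(dataset, settings), dataset.exposure, settings.learners_exposure,
            "binomial", cv_folds=3, random_state=seed,
        )
        outcome = fit_superlearner(
            _outcome_design(dataset, settings), scale_outcome(dataset.outcome, scale),
            settings.learners_exposure, "gaussian", cv_folds=3, random_state=seed + 1,
        )
        return exposure, outcome, scale

    def test_deterministic_given_models(self, small_dataset):
        exposure, outcome, scale = self._models(small_dataset)
        rows = np.arange(small_dataset.n)
        e1 = run_split_tmle(small_dataset, rows, exposure, outcome, scale)
        e2 = run_split_tmle(small_dataset, rows, exposure, outcome, scale)
        assert e1 == e2

    def test_n_eval_recorded(self, small_dataset):
        exposure, outcome, scale = self._models(small_dataset)
        rows = np.arange(80)
        est = run_split_tmle(small_dataset, rows, exposure, outcome, scale)
        assert est.n_eval == 80

    def test_degenerate_arm_raises(self, small_dataset):
        exposure, outcome, scale = self._models(small_dataset)
        rows = np.flatnonzero(small_dataset.exposure == 1)[:20]
        with pytest.raises(EstimationError, match="single exposure arm"):
            run_split_tmle(small_dataset, rows, exposure, outcome, scale)

    def test_identity_fluctuation_equals_g_computation(self, small_dataset):
        # if eps == 0 the local ATE is the plain g-computation estimate
        exposure, outcome, scale = self._models(small_dataset)
        details = _split_tmle_details(
            small_dataset, np.arange(small_dataset.n), exposure, outcome, scale
        )
        nuis = details["nuisance"]
        gcomp = local_ate(nuis.mu1, nuis.mu0, scale)
        forced = update_predictions(nuis.mu1, nuis.mu0, nuis.pi_hat, FluctuationFit(0.0, 0.0))
        assert local_ate(forced[0], forced[1], scale) == pytest.approx(gcomp, abs=1e-12)

    def test_mu_a_consistency(self, small_dataset):
        exposure, outcome, scale = self._models(small_dataset)
        details = _split_tmle_details(
            small_dataset, np.arange(small_dataset.n), exposure, outcome, scale
        )
        nuis = details["nuisance"]
        a = details["a"]
        np.testing.assert_array_equal(nuis.mu_a[a == 1], nuis.mu1[a == 1])
        np.testing.assert_array_equal(nuis.mu_a[a == 0], nuis.mu0[a == 0])


class TestTrueNuisanceConsistency:
    @pytest.mark.parametrize("n", [500, 2000, 8000])
    def test_true_nuisances_recover_theta(self, n):
        # chain the engine primitives with the DGP's true nuisance functions;
        # the estimate must sit within 4 influence-function SEs of theta0
        dataset, truth = generate_dataset(DGPConfig(n=n, true_ate=1.0, seed=n))
        scale = dataset.outcome_scale()
        clip = lambda v: np.clip((v - scale.y_min) / scale.span, 1e-5, 1 - 1e-5)
        y_star = scale_outcome(dataset.outcome, scale)
        pi = bound_propensity(truth["propensity"], propensity_bound(n))
        mu1, mu0 = clip(truth["mu1"]), clip(truth["mu0"])
        a = dataset.exposure.astype(float)
        mu_a = np.where(a == 1, mu1, mu0)
        h1, h0 = clever_covariates(a, pi)
        fit = fit_fluctuation(y_star, h1, h0, mu_a)
        u1, u0 = update_predictions(mu1, mu0, pi, fit)
        ate = local_ate(u1, u0, scale)
        var = eif_variance(
            dataset.outcome, a, pi, u1 * scale.span + scale.y_min,
            u0 * scale.span + scale.y_min, ate, n_total=n,
        )
        assert abs(ate - 1.0) < 4.0 * np.sqrt(var)
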