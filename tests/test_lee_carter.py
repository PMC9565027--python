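import numpy as np
import pytest

from lcmort import (FitWeights, LCFitError, LCParams, MortalitySurface,
                    central_rates, fit_lc_poisson, fitted_log_rates, init_lc,
                    normalize_lc, poisson_deviance, weights_from_mask)


def surface_from_params(params, N, years_start=2000):
    """Noiseless surface: D = N * exp(alpha + beta*kappa) exactly."""
    A, T = params.alpha.size, params.kappa.size
    N = np.broadcast_to(np.asarray(N, dtype=float), (A, T)).copy()
    D = N * np.exp(fitted_log_rates(params))
    return MortalitySurface(
        ages=np.arange(A), years=np.arange(years_start, years_start + T),
        deaths=D, exposures=N, observed_mask=np.ones((A, T), dtype=bool),
    )


def random_params(A, T, seed):
    rng = np.random.default_rng(seed)
    alpha = rng.uniform(-6, -3, A)
    beta = rng.dirichlet(np.ones(A) * 5)
    kappa = rng.normal(0, 3, T)
    return normalize_lc(LCParams(alpha, beta, kappa))


class TestWeights:
    def test_fully_observed_gives_all_ones(self, small_surface):
        assert weights_from_mask(small_surface).w.sum() == 6

    def test_masked_cell_zero_unless_imputed(self, small_surface):
        small_surface.observed_mask[1, 0] = False
        small_surface.imputed_mask[1, 0] = True
        assert weights_from_mask(small_surface, use_imputed=False).w[1, 0] == 0
        assert weights_from_mask(small_surface, use_imputed=True).w[1, 0] == 1

    def test_all_missing_row_unidentifiable(self, small_surface):
        small_surface.observed_mask[1, :] = False
        with pytest.raises(LCFitError, match="ages \\[1\\]"):
            weights_from_mask(small_surface)

    def test_non_binary_weights_rejected(self):
        with pytest.raises(LCFitError):
            FitWeights(np.array([[0.5]]))


class TestInit:
    def test_single_year_forces_zero_kappa(self):
        p = random_params(4, 1, 0)
        s = surface_from_params(p, 1e5)
        init = init_lc(central_rates(s), weights_from_mask(s))
        np.testing.assert_allclose(init.kappa, [0.0], atol=1e-12)
        np.testing.assert_allclose(init.alpha, np.log(s.deaths[:, 0] / 1e5))

    def test_exact_recovery_with_uniform_beta(self):
        A, T = 6, 5
        rng = np.random.default_rng(1)
        truth = normalize_lc(LCParams(rng.uniform(-6, -3, A),
                                      np.full(A, 1.0 / A), rng.normal(0, 2, T)))
        s = surface_from_params(truth, 1e6)
        init = init_lc(central_rates(s), weights_from_mask(s))
        np.testing.assert_allclose(init.alpha, truth.alpha, atol=1e-10)
        np.testing.assert_allclose(init.kappa, truth.kappa, atol=1e-8)

    def test_constant_rates(self):
        s = MortalitySurface(np.arange(3), np.arange(2000, 2004),
                             np.full((3, 4), 50.0), np.full((3, 4), 1e4),
                             np.ones((3, 4), dtype=bool))
        init = init_lc(central_rates(s), weights_from_mask(s))
        np.testing.assert_allclose(init.alpha, np.log(0.005), atol=1e-12)
        np.testing.assert_allclose(init.kappa, 0.0, atol=1e-12)

    def test_nonfinite_log_rate_rejected(self, small_surface):
        small_surface.deaths[0, 0] = 0.0
        with pytest.raises(LCFitError, match="non-finite"):
            init_lc(central_rates(small_surface), weights_from_mask(small_surface))


class TestDeviance:
    def test_zero_iff_equal(self):
        D = np.array([[3.0, 7.0]])
        w = FitWeights(np.ones((1, 2)))
        assert poisson_deviance(D, D.copy(), w) == 0.0

    def test_hand_value_single_cell(self):
        w = FitWeights(np.ones((1, 1)))
        val = poisson_deviance(np.array([[2.0]]), np.array([[1.0]]), w)
        assert val == pytest.approx(2 * (2 * np.log(2) - 1), abs=1e-12)

    def test_zero_weight_cell_contributes_nothing(self):
        w = FitWeights(np.zeros((1, 1)))
        assert poisson_deviance(np.array([[5.0]]), np.array([[0.1]]), w) == 0.0

    def test_zero_count_term(self):
        w = FitWeights(np.ones((1, 1)))
        assert poisson_deviance(np.array([[0.0]]), np.array([[3.0]]), w) == pytest.approx(6.0)

    def test_nonpositive_fitted_rejected(self):
        w = FitWeights(np.ones((1, 1)))
        with pytest.raises(LCFitError):
            poisson_deviance(np.array([[1.0]]), np.array([[0.0]]), w)


class TestNormalize:
    def test_hand_example(self):
        out = normalize_lc(LCParams([0.0, 0.0], [2.0, 2.0], [1.0, -1.0]))
        np.testing.assert_allclose(out.beta, [0.5, 0.5])
        np.testing.assert_allclose(out.kappa, [4.0, -4.0])
        np.testing.assert_allclose(out.alpha, [0.0, 0.0])

    def test_already_normalized_unchanged(self):
        p = random_params(4, 3, 2)
        out = normalize_lc(p)
        np.testing.assert_allclose(out.alpha, p.alpha, atol=1e-12)
        np.testing.assert_allclose(out.beta, p.beta, atol=1e-12)
        np.testing.assert_allclose(out.kappa, p.kappa, atol=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_fitted_rates_invariant(self, seed):
        rng = np.random.default_rng(seed)
        p = LCParams(rng.normal(-4, 1, 5), rng.uniform(0.1, 2, 5), rng.normal(0, 4, 6))
        delta = fitted_log_rates(normalize_lc(p)) - fitted_log_rates(p)
        assert np.abs(delta).max() <= 1e-12

    def test_zero_beta_sum_degenerate(self):
        with pytest.raises(LCFitError):
            normalize_lc(LCParams([0.0, 0.0], [1.0, -1.0], [0.0, 0.0]))


class TestFittedLogRates:
    def test_zero_kappa_gives_alpha_columns(self):
        p = LCParams([-4.0, -3.0], [0.5, 0.5], [0.0, 0.0, 0.0])
        np.testing.assert_allclose(fitted_log_rates(p),
                                   np.tile([[-4.0], [-3.0]], (1, 3)))

    def test_hand_matrix(self):
        p = LCParams([-5.0, -4.0], [0.25, 0.75], [2.0, -2.0])
        np.testing.assert_allclose(fitted_log_rates(p),
                                   [[-4.5, -5.5], [-2.5, -5.5]])


class TestFit:
    def test_noiseless_recovery(self):
        truth = random_params(10, 8, 3)
        s = surface_from_params(truth, 1e6)
        fit = fit_lc_poisson(s, weights_from_mask(s), tol=1e-12)
        assert fit.converged
        np.testing.assert_allclose(fit.params.alpha, truth.alpha, atol=1e-6)
        np.testing.assert_allclose(fit.params.beta, truth.beta, atol=1e-6)
        np.testing.assert_allclose(fit.params.kappa, truth.kappa, atol=1e-6)
        assert fit.deviance < 1e-8

    def test_single_age_closed_form(self):
        rng = np.random.default_rng(4)
        T = 6
        N = np.full((1, T), 1e5)
        D = rng.poisson(50, (1, T)).astype(float)
        s = MortalitySurface(np.array([40]), np.arange(2000, 2000 + T),
                             D, N, np.ones((1, T), dtype=bool))
        fit = fit_lc_poisson(s, weights_from_mask(s), tol=1e-12)
        logm = np.log(D[0] / N[0])
        np.testing.assert_allclose(fit.params.beta, [1.0])
        np.testing.assert_allclose(fit.params.kappa, logm - logm.mean(), atol=1e-8)
        np.testing.assert_allclose(fit.params.alpha, [logm.mean()], atol=1e-8)

    def test_deviance_trace_non_increasing(self):
        rng = np.random.default_rng(5)
        truth = random_params(8, 6, 5)
        s = surface_from_params(truth, 5e4)
        s.deaths = rng.poisson(s.deaths).astype(float)
        fit = fit_lc_poisson(s, weights_from_mask(s))
        assert np.all(np.diff(fit.deviance_trace) <= 1e-9)
        assert fit.deviance == pytest.approx(fit.deviance_trace[-1], abs=1e-6)

    def test_zero_weight_equals_deleted_data(self):
        """Missing-data contract: w=0 must behave exactly like absent data."""
        rng = np.random.default_rng(6)
        truth = random_params(5, 4, 6)
        s = surface_from_params(truth, 1e5)
        s.deaths = rng.poisson(s.deaths).astype(float)

        w = np.ones((5, 4))
        w[2, 1] = 0.0
        fit_w = fit_lc_poisson(s, FitWeights(w), tol=1e-10)

        s2 = s.copy()
        s2.deaths[2, 1] = 12345.0  # arbitrary garbage behind the zero weight
        fit_d = fit_lc_poisson(s2, FitWeights(w.copy()), tol=1e-10)

        np.testing.assert_allclose(fit_w.params.alpha, fit_d.params.alpha, atol=1e-10)
        np.testing.assert_allclose(fit_w.params.beta, fit_d.params.beta, atol=1e-10)
        np.testing.assert_allclose(fit_w.params.kappa, fit_d.params.kappa, atol=1e-10)

    def test_returned_params_normalized(self):
        truth = random_params(6, 5, 7)
        s = surface_from_params(truth, 1e5)
        fit = fit_lc_poisson(s, weights_from_mask(s))
        assert abs(fit.params.beta.sum() - 1) <= 1e-10
        assert abs(fit.params.kappa.sum()) <= 1e-8

    def test_zero_death_cells_handled(self):
        """Observed zero counts are legitimate data for the Poisson fit."""
        truth = random_params(5, 4, 8)
        s = surface_from_params(truth, 1e5)
        s.deaths = np.floor(s.deaths)
        s.deaths[1, 2] = 0.0
        fit = fit_lc_poisson(s, weights_from_mask(s))
        assert fit.converged and np.isfinite(fit.deviance)

    def test_identifiability_violation_rejected(self, small_surface):
        w = np.ones((3, 2))
        w[:, 0] = 0.0
        with pytest.raises(LCFitError, match="years"):
            fit_lc_poisson(small_surface, FitWeights(w))
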