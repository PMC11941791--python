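import numpy as np
import pytest
import scipy.linalg

from fdmort.exceptions import FitError, ValidationError
from fdmort.hu_fpca import build_basis, fit_hu, forecast_hu, variance_table
from fdmort.io_mortality import AgeGrid, MortalitySurface
from fdmort.lee_carter import fit_lc, fitted_log_rates

from conftest import random_surface


def make_component_surface(mu, loadings, scores, first_year=2000):
    """Surface with log rates mu + loadings @ scores (exact construction)."""
    n_ages = len(mu)
    logm = mu[:, None] + loadings @ scores
    ages = AgeGrid(tuple(f"g{i}" for i in range(n_ages)),
                   np.arange(n_ages, dtype=float) * 5 + 2)
    years = np.arange(first_year, first_year + logm.shape[1])
    return MortalitySurface(ages, years, np.exp(logm))


def eigh_oracle(C, n_years):
    """Covariance eigen-decomposition oracle, independent of the fit path."""
    cov = C @ C.T / (n_years - 1)
    w, V = scipy.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    return w[order], V[:, order]


class TestFitHU:
    def test_single_component_identity(self):
        mu = np.log(np.array([0.02, 0.005, 0.01, 0.03]))
        beta = np.array([[0.5], [0.5], [-0.5], [-0.5]])
        kappa = np.array([[0.3, -0.1, 0.2, -0.4, 0.0, 0.0]])
        kappa -= kappa.mean(axis=1, keepdims=True)
        s = make_component_surface(mu, beta, kappa)
        fit = fit_hu(s, K=1)
        np.testing.assert_allclose(fit.variance_explained, [1.0], atol=1e-10)
        np.testing.assert_allclose(fit.fitted_log(), np.log(s.rates),
                                   atol=1e-10)

    def test_matches_covariance_eigh_oracle(self):
        s = random_surface(0, n_ages=5, n_years=10)
        fit = fit_hu(s, K=3)
        L = np.log(s.rates)
        C = L - L.mean(axis=1, keepdims=True)
        w, V = eigh_oracle(C, s.n_years)
        np.testing.assert_allclose(fit.eigenvalues[:3], w[:3], atol=1e-8)
        for k in range(3):
            v = V[:, k] * np.sign(V[:, k].sum() or 1.0)
            np.testing.assert_allclose(fit.loadings[:, k], v, atol=1e-8)
            np.testing.assert_allclose(fit.scores[k], v @ C, atol=1e-8)

    def test_full_rank_reconstruction(self):
        s = random_surface(1, n_ages=5, n_years=10)
        fit = fit_hu(s, K=min(5, 9))
        assert np.linalg.norm(fit.residuals) < 1e-8

    def test_orthonormal_loadings_and_uncorrelated_scores(self):
        for seed in range(5):
            s = random_surface(seed, n_ages=6, n_years=12)
            fit = fit_hu(s, K=4)
            gram = fit.loadings.T @ fit.loadings
            np.testing.assert_allclose(gram, np.eye(4), atol=1e-8)
            cov = np.cov(fit.scores)
            off = cov - np.diag(np.diag(cov))
            assert np.max(np.abs(off)) < 1e-6 * max(np.diag(cov))

    def test_k1_data_driven_equals_lee_carter(self):
        s = random_surface(2, n_ages=8, n_years=15)
        hu = fit_hu(s, K=1)
        lc = fit_lc(s)
        np.testing.assert_allclose(
            hu.mu_x[:, None] + hu.loadings @ hu.scores,
            fitted_log_rates(lc), atol=1e-8,
        )

    def test_k_out_of_range_rejected(self):
        s = random_surface(3, n_ages=4, n_years=6)
        with pytest.raises(ValidationError):
            fit_hu(s, K=0)
        with pytest.raises(ValidationError):
            fit_hu(s, K=5)

    def test_n_basis_above_age_points_rejected(self):
        s = random_surface(4, n_ages=5, n_years=10)
        with pytest.raises(ValidationError):
            fit_hu(s, K=2, basis_type="bspline", n_basis=9)


class TestBases:
    @pytest.mark.parametrize("basis", ["bspline", "fourier", "cubic_spline"])
    def test_basis_shape_and_rank(self, basis):
        x = np.linspace(0.5, 90.0, 19)
        B = build_basis(x, basis, 7)
        assert B.shape == (19, 7)
        assert np.linalg.matrix_rank(B) == 7

    def test_all_bases_agree_on_smooth_curves(self):
        # mortality curves are smooth over age, so with enough basis
        # functions to span the curves every regime reproduces the
        # data-driven variance decomposition within 1 percentage point
        from fdmort.io_mortality import default_age_grid
        from fdmort.synthetic_data import default_baseline_log_rates

        grid = default_age_grid()
        x = (grid.midpoints - grid.midpoints[0]) / np.ptp(grid.midpoints)
        b1 = 0.5 + x
        b1 /= np.linalg.norm(b1)
        b2 = (x - 0.5) ** 2
        b2 -= (b2 @ b1) * b1
        b2 /= np.linalg.norm(b2)
        rng = np.random.default_rng(5)
        scores = np.vstack([0.5 * np.cumsum(rng.standard_normal(23)),
                            0.3 * rng.standard_normal(23)])
        logm = (default_baseline_log_rates()[:, None]
                + np.column_stack([b1, b2]) @ scores
                + 0.01 * rng.standard_normal((19, 23)))
        s = MortalitySurface(grid, np.arange(1991, 2014), np.exp(logm))
        ref = fit_hu(s, K=3).variance_explained * 100
        for basis in ("bspline", "fourier", "cubic_spline"):
            got = fit_hu(s, K=3, basis_type=basis,
                         n_basis=19).variance_explained * 100
            np.testing.assert_allclose(got, ref, atol=1.0)  # within 1 pp


class TestVarianceTable:
    def test_single_component_is_100(self):
        mu = np.log(np.array([0.02, 0.005, 0.01]))
        beta = np.array([[0.7], [0.1], [0.2]])
        kappa = np.array([[0.5, -0.5, 0.2, -0.2, 0.0]])
        fit = fit_hu(make_component_surface(mu, beta, kappa), K=1)
        assert variance_table(fit) == [(1, pytest.approx(100.0, abs=1e-8))]

    def test_matches_eigenvalue_ratios(self):
        s = random_surface(6, n_ages=5, n_years=10)
        fit = fit_hu(s, K=3)
        L = np.log(s.rates)
        C = L - L.mean(axis=1, keepdims=True)
        w, _ = eigh_oracle(C, s.n_years)
        w = w[w > 1e-12 * w[0]]
        expected = 100 * w[:3] / w.sum()
        got = [pct for _, pct in variance_table(fit)]
        np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_full_set_sums_to_100(self):
        s = random_surface(7, n_ages=5, n_years=10)
        fit = fit_hu(s, K=5)
        total = sum(pct for _, pct in variance_table(fit))
        assert total == pytest.approx(100.0, abs=1e-6)


class TestForecastHU:
    def test_constant_scores_forecast_flat(self):
        mu = np.log(np.array([0.02, 0.005, 0.01, 0.008]))
        rng = np.random.default_rng(0)
        logm = mu[:, None] + 0.001 * rng.standard_normal((4, 8))
        ages = AgeGrid(("a", "b", "c", "d"), np.array([1.0, 2, 3, 4]))
        s = MortalitySurface(ages, np.arange(2000, 2008), np.exp(logm))
        fit = fit_hu(s, K=2)
        const_scores = np.tile(fit.scores[:, -1:], (1, s.n_years))
        from dataclasses import replace
        fit = replace(fit, scores=const_scores)
        fc = forecast_hu(fit, 3, score_method="lr")
        last_fitted = np.exp(fit.fitted_log()[:, -1])
        for j in range(3):
            np.testing.assert_allclose(fc.rates[:, j], last_fitted, rtol=1e-8)

    def test_linear_first_score_lr_exact(self):
        mu = np.log(np.array([0.02, 0.005, 0.01, 0.008]))
        beta = np.array([[0.6], [0.2], [-0.1], [0.3]])
        t = np.arange(10, dtype=float)
        kappa = (0.08 * (t - t.mean()))[None, :]
        s = make_component_surface(mu, beta, kappa)
        fit = fit_hu(s, K=1)
        fc = forecast_hu(fit, 4, score_method="lr")
        future_kappa = 0.08 * (np.arange(10, 14) - t.mean())
        expected = np.exp(mu[:, None] + beta @ future_kappa[None, :])
        np.testing.assert_allclose(fc.rates, expected, rtol=1e-8)

    def test_failure_names_component(self):
        s = random_surface(8, n_ages=4, n_years=7)  # too short for gam
        fit = fit_hu(s, K=2)
        with pytest.raises(FitError, match="component 1"):
            forecast_hu(fit, 3, score_method="gam")

    def test_arima_beats_frozen_last_value_baseline(self):
        # two components (rw-drift + AR(1)): ARIMA score forecasts must
        # beat the "freeze last value" baseline in most replicates
        from fdmort.validation import evaluate_forecast, split_surface

        mu = np.log(np.array([0.03, 0.01, 0.004, 0.009, 0.02]))
        b1 = np.array([0.6, 0.5, 0.4, 0.35, 0.3])
        b1 /= np.linalg.norm(b1)
        b2 = np.array([0.5, -0.2, -0.6, 0.1, 0.4])
        b2 -= (b2 @ b1) * b1
        b2 /= np.linalg.norm(b2)
        wins = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            k1 = np.cumsum(-0.15 + 0.05 * rng.standard_normal(33))
            k2 = np.zeros(33)
            for t in range(1, 33):
                k2[t] = 0.7 * k2[t - 1] + 0.05 * rng.standard_normal()
            surface = make_component_surface(
                mu, np.column_stack([b1, b2]), np.vstack([k1, k2]))
            train, test = split_surface(surface, surface.years[22])
            fit = fit_hu(train, K=2)
            fc = forecast_hu(fit, 10, score_method="arima")
            fc = MortalitySurface(fc.ages, test.years, fc.rates)
            frozen = MortalitySurface(
                test.ages, test.years,
                np.tile(np.exp(fit.fitted_log()[:, -1:]), (1, 10)))
            m_arima = evaluate_forecast(test, fc).overall
            m_frozen = evaluate_forecast(test, frozen).overall
            wins += m_arima < m_frozen
        assert wins >= 0.80 * n_seeds
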