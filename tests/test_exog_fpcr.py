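from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from fdmort.exceptions import ValidationError
from fdmort.exog_fpcr import (
    bootstrap_percentile_interval,
    bootstrap_regression,
    factor_contributions,
    fit_score_regression,
    forecast_scores_exog,
)
from fdmort.io_mortality import ExogenousTable


def table(years, **factors):
    return ExogenousTable(pd.DataFrame(factors, index=list(years)))


@pytest.fixture
def three_factor_table():
    rng = np.random.default_rng(0)
    years = range(1991, 2014)
    return table(years,
                 GDP=np.cumsum(rng.uniform(50, 150, 23)) + 1000,
                 Doctors=3.5 + 0.1 * rng.standard_normal(23),
                 Popul=15e6 + 1e5 * rng.standard_normal(23))


def brute_force_lmg(y, Z):
    """Independent LMG oracle: explicit R^2 per subset, all orderings."""
    n, p = Z.shape

    def r2(cols):
        if not cols:
            return 0.0
        X = np.column_stack([np.ones(n), Z[:, cols]])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        yc = y - y.mean()
        return 1.0 - (resid @ resid) / (yc @ yc)

    shares = np.zeros(p)
    perms = list(permutations(range(p)))
    for perm in perms:
        prev = 0.0
        for i, idx in enumerate(perm):
            cur = r2(sorted(perm[:i + 1]))
            shares[idx] += cur - prev
            prev = cur
    shares /= len(perms)
    return 100.0 * shares / r2(list(range(p)))


class TestFitScoreRegression:
    def test_noiseless_single_factor_recovery(self):
        z = np.linspace(0, 10, 12)
        t = table(range(2000, 2012), z1=z)
        fit = fit_score_regression(2 + 3 * z, t)
        assert fit.intercept == pytest.approx(2.0, abs=1e-10)
        assert fit.coefficients["z1"] == pytest.approx(3.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_duplicated_factor_rejected(self):
        z = np.linspace(0, 10, 12)
        t = table(range(2000, 2012), a=z, b=z)
        with pytest.raises(ValidationError, match="'a'.*'b'"):
            fit_score_regression(2 + 3 * z, t)

    def test_coefficient_recovery_monte_carlo(self):
        # kappa = 1 + 0.5 z1 - 2 z2 + N(0, 0.3), n=23
        n = 23
        g1, g2 = [], []
        base = np.random.default_rng(99)
        z1 = base.uniform(0, 5, n)
        z2 = base.uniform(-2, 2, n)
        t = table(range(1991, 1991 + n), z1=z1, z2=z2)
        for seed in range(500):
            rng = np.random.default_rng(seed)
            y = 1 + 0.5 * z1 - 2 * z2 + 0.3 * rng.standard_normal(n)
            fit = fit_score_regression(y, t)
            g1.append(fit.coefficients["z1"])
            g2.append(fit.coefficients["z2"])
        for est, truth in ((g1, 0.5), (g2, -2.0)):
            se = np.std(est) / np.sqrt(len(est))
            assert abs(np.mean(est) - truth) <= 2 * se + 1e-12

    def test_standardization_leaves_fit_statistics(self, three_factor_table):
        rng = np.random.default_rng(1)
        df = three_factor_table.data
        y = (0.001 * df["GDP"] - 2 * df["Doctors"]
             + 0.3 * rng.standard_normal(len(df))).to_numpy()
        raw = fit_score_regression(y, three_factor_table)
        std_tab = ExogenousTable((df - df.mean()) / df.std())
        std = fit_score_regression(y, std_tab)
        assert std.r_squared == pytest.approx(raw.r_squared, abs=1e-10)
        assert std.f_pvalue == pytest.approx(raw.f_pvalue, abs=1e-10)
        for name in raw.factor_names:
            assert std.contributions[name] == pytest.approx(
                raw.contributions[name], abs=1e-8)


class TestContributions:
    def test_single_factor_is_100(self):
        z = np.linspace(0, 10, 12)
        t = table(range(2000, 2012), z1=z)
        rng = np.random.default_rng(0)
        fit = fit_score_regression(2 + 3 * z + 0.1 * rng.standard_normal(12), t)
        assert fit.contributions["z1"] == pytest.approx(100.0, abs=1e-10)

    def test_matches_brute_force_three_factors(self, three_factor_table):
        rng = np.random.default_rng(2)
        df = three_factor_table.data
        y = (0.0005 * df["GDP"] + 1.5 * df["Doctors"]
             - 1e-6 * df["Popul"]
             + 0.5 * rng.standard_normal(len(df))).to_numpy()
        fit = fit_score_regression(y, three_factor_table)
        oracle = brute_force_lmg(y, df.to_numpy())
        got = [fit.contributions[n] for n in fit.factor_names]
        np.testing.assert_allclose(got, oracle, atol=1e-10)
        assert sum(got) == pytest.approx(100.0, abs=1e-6)

    def test_orthogonal_factors_proportional_to_marginal_r2(self):
        n = 30
        rng = np.random.default_rng(3)
        z1 = rng.standard_normal(n)
        z2 = rng.standard_normal(n)
        z1 -= z1.mean()
        z2 -= z2.mean()
        z2 -= (z2 @ z1) / (z1 @ z1) * z1       # exactly orthogonal
        y = 2 * z1 + 1 * z2 + 0.2 * rng.standard_normal(n)
        t = table(range(2000, 2000 + n), z1=z1, z2=z2)
        fit = fit_score_regression(y, t)

        def marginal_r2(z):
            X = np.column_stack([np.ones(n), z])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            yc = y - y.mean()
            return 1 - (resid @ resid) / (yc @ yc)

        r1, r2_ = marginal_r2(z1), marginal_r2(z2)
        expected = 100 * np.array([r1, r2_]) / (r1 + r2_)
        got = [fit.contributions["z1"], fit.contributions["z2"]]
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_permutation_invariance(self, three_factor_table):
        rng = np.random.default_rng(4)
        df = three_factor_table.data
        y = (0.0005 * df["GDP"] + 1.5 * df["Doctors"]
             + 0.4 * rng.standard_normal(len(df))).to_numpy()
        a = fit_score_regression(y, three_factor_table).contributions
        shuffled = ExogenousTable(df[["Popul", "GDP", "Doctors"]])
        b = fit_score_regression(y, shuffled).contributions
        for name in a:
            assert b[name] == pytest.approx(a[name], abs=1e-10)

    def test_recompute_matches_fit(self, three_factor_table):
        rng = np.random.default_rng(5)
        df = three_factor_table.data
        y = (0.0003 * df["GDP"] + 0.6 * rng.standard_normal(len(df))).to_numpy()
        fit = fit_score_regression(y, three_factor_table)
        again = factor_contributions(fit, y, three_factor_table)
        assert again == fit.contributions


class TestBootstrap:
    def test_same_seed_identical(self, three_factor_table):
        rng = np.random.default_rng(6)
        df = three_factor_table.data
        y = (0.0005 * df["GDP"] + rng.standard_normal(len(df))).to_numpy()
        a = bootstrap_regression(y, three_factor_table, B=200, seed=11)
        b = bootstrap_regression(y, three_factor_table, B=200, seed=11)
        np.testing.assert_array_equal(a.bootstrap_coefficients,
                                      b.bootstrap_coefficients)

    def test_noiseless_replicates_equal_truth(self):
        z = np.linspace(0, 10, 15)
        t = table(range(2000, 2015), z1=z)
        fit = bootstrap_regression(2 + 3 * z, t, B=200, seed=0)
        np.testing.assert_allclose(fit.bootstrap_coefficients, 3.0, atol=1e-8)

    def test_small_b_rejected(self, three_factor_table):
        y = np.arange(23.0)
        with pytest.raises(ValidationError):
            bootstrap_regression(y, three_factor_table, B=50)

    def test_interval_brackets_estimate(self, three_factor_table):
        rng = np.random.default_rng(7)
        df = three_factor_table.data
        y = (0.0005 * df["GDP"] + rng.standard_normal(len(df))).to_numpy()
        fit = bootstrap_regression(y, three_factor_table, B=500, seed=1)
        lo, hi = bootstrap_percentile_interval(fit, "GDP")
        assert lo < hi


class TestForecastScoresExog:
    def test_training_year_values_reproduce_fitted(self):
        rng = np.random.default_rng(8)
        z = rng.uniform(0, 5, 12)
        t = table(range(2000, 2012), z1=z)
        y = 1 + 2 * z + 0.1 * rng.standard_normal(12)
        fit = fit_score_regression(y, t)
        fc = forecast_scores_exog(fit, t)
        fitted = y - fit.residuals
        np.testing.assert_allclose(fc.to_numpy(), fitted, atol=1e-10)

    def test_missing_factor_rejected(self):
        z = np.linspace(0, 10, 12)
        t = table(range(2000, 2012), z1=z)
        fit = fit_score_regression(2 + 3 * z, t)
        other = table(range(2012, 2015), z9=np.arange(3.0))
        with pytest.raises(ValidationError, match="z1"):
            forecast_scores_exog(fit, other)

    def test_exogenous_beats_arima_under_regime_change(self):
        # kappa depends linearly on z; z rises on the training frame and
        # falls on the test frame.  The covariate model knows the turn,
        # pure extrapolation cannot.
        from fdmort.score_models import forecast_arima_auto
        from fdmort.validation import mape

        years = np.arange(1991, 2024)
        z = np.concatenate([np.linspace(0, 10, 23),
                            np.linspace(9.5, 4, 10)])
        rng = np.random.default_rng(9)
        kappa = 50 + 3 * z + 0.05 * rng.standard_normal(33)
        t_train = table(years[:23], z1=z[:23])
        t_test = table(years[23:], z1=z[23:])
        fit = fit_score_regression(kappa[:23], t_train)
        exog_fc = forecast_scores_exog(fit, t_test).to_numpy()
        arima_fc = forecast_arima_auto(kappa[:23], 10).point
        assert mape(kappa[23:], exog_fc) < mape(kappa[23:], arima_fc)

    def test_two_step_reconstruction_exact_when_r2_is_1(self):
        # factors that ARE the scores: every regression has R^2 = 1, so the
        # exogenous forecast reproduces the fitted surface exactly
        from fdmort.hu_fpca import fit_hu

        from conftest import random_surface

        s = random_surface(10, n_ages=6, n_years=12)
        fit = fit_hu(s, K=2)
        t = table(s.years, f1=fit.scores[0], f2=fit.scores[1])
        recon = np.empty_like(fit.scores)
        for k in range(2):
            reg = fit_score_regression(fit.scores[k], t)
            assert reg.r_squared == pytest.approx(1.0, abs=1e-10)
            recon[k] = forecast_scores_exog(reg, t).to_numpy()
        log_fc = fit.mu_x[:, None] + fit.loadings @ recon
        np.testing.assert_allclose(log_fc, fit.fitted_log(), atol=1e-8)
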