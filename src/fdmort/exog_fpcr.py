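"""Two-step functional principal component regression on exogenous factors.

After an FPCA of the mortality surface, each score series kappa_{k,t} is
regressed on yearly exogenous factors z_1..z_n (here typically GDP per
capita, doctor density and population size):

    kappa_{k,t} = alpha + gamma_1 z_1t + ... + gamma_n z_nt + eps_t

Forecast scores are then alpha + sum_i gamma_i z_it evaluated at future
factor values, so curve forecasts inherit information from the covariates
instead of pure time-series extrapolation.

Per-factor "contribution" percentages are computed with the LMG relative
importance decomposition: each factor's sequential R^2 increment averaged
over all orderings of entry.  LMG is order-invariant and its shares sum to
100% of the explained variance.  Uncertainty is assessed by case-resampling
bootstrap of the regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FitError, ValidationError
from .io_mortality import ExogenousTable

__all__ = [
    "ScoreRegression",
    "fit_score_regression",
    "factor_contributions",
    "bootstrap_regression",
    "forecast_scores_exog",
    "bootstrap_percentile_interval",
]

_MAX_LMG_FACTORS = 8


@dataclass(frozen=True)
class ScoreRegression:
    """OLS fit of one score series on named exogenous factors."""

    component_index: int
    factor_names: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float]
    p_values: dict[str, float]
    intercept_p_value: float
    r_squared: float
    f_pvalue: float
    contributions: dict[str, float]  # percentages of explained variance
    residuals: np.ndarray
    bootstrap_coefficients: np.ndarray | None = None  # B x n_factors

    def predict(self, factors: Mapping[str, np.ndarray] | pd.DataFrame) -> np.ndarray:
        z = np.column_stack([np.asarray(factors[n], float)
                             for n in self.factor_names])
        gamma = np.array([self.coefficients[n] for n in self.factor_names])
        return self.intercept + z @ gamma


def _design(scores: Sequence[float], exog: ExogenousTable,
            score_years: Sequence[int] | None) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(scores, dtype=float)
    if y.ndim != 1:
        raise ValidationError("scores must be a single 1-d series")
    if score_years is not None:
        tab = exog.subset_years(score_years)
    else:
        if len(exog.years) != len(y):
            raise ValidationError(
                f"exogenous table has {len(exog.years)} years but the score "
                f"series has {len(y)}; pass score_years to align"
            )
        tab = exog
    Z = tab.data.to_numpy(dtype=float)
    if Z.shape[1] >= len(y) - 1:
        raise ValidationError(
            f"{Z.shape[1]} factors with only {len(y)} observations"
        )
    return y, Z


def _check_collinear(Z: np.ndarray, names: Sequence[str]) -> None:
    X = np.column_stack([np.ones(len(Z)), Z])
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    zs = (Z - Z.mean(0)) / np.where(Z.std(0) > 0, Z.std(0), 1.0)
    corr = zs.T @ zs / len(Z)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if abs(corr[i, j]) > 1 - 1e-10:
                raise ValidationError(
                    f"collinear factors: {names[i]!r} and {names[j]!r}"
                )
    raise ValidationError("rank-deficient design matrix (collinear factors)")


def fit_score_regression(scores: Sequence[float], exog: ExogenousTable,
                         score_years: Sequence[int] | None = None,
                         component_index: int = 1) -> ScoreRegression:
    """OLS of one FPC score series on all factors in ``exog``."""
    import statsmodels.api as sm

    y, Z = _design(scores, exog, score_years)
    names = exog.factor_names
    _check_collinear(Z, names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.OLS(y, sm.add_constant(Z)).fit()
    params = np.asarray(res.params)
    pvals = np.asarray(res.pvalues)
    contributions = _lmg_contributions(y, Z, names)
    return ScoreRegression(
        component_index=int(component_index),
        factor_names=names,
        intercept=float(params[0]),
        coefficients={n: float(params[i + 1]) for i, n in enumerate(names)},
        p_values={n: float(pvals[i + 1]) for i, n in enumerate(names)},
        intercept_p_value=float(pvals[0]),
        r_squared=float(res.rsquared),
        f_pvalue=float(res.f_pvalue) if np.isfinite(res.f_pvalue) else float("nan"),
        contributions=contributions,
        residuals=np.asarray(res.resid),
    )


def _subset_r2(y: np.ndarray, Z: np.ndarray, cols: tuple[int, ...],
               cache: dict) -> float:
    if cols in cache:
        return cache[cols]
    yc = y - y.mean()
    tss = float(yc @ yc)
    if tss <= 0:
        cache[cols] = 0.0
        return 0.0
    if not cols:
        cache[cols] = 0.0
        return 0.0
    X = np.column_stack([np.ones(len(y)), Z[:, list(cols)]])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    r2 = 1.0 - float(resid @ resid) / tss
    cache[cols] = r2
    return r2


def _lmg_contributions(y: np.ndarray, Z: np.ndarray,
                       names: Sequence[str]) -> dict[str, float]:
    """LMG shares as percentages of explained variance (sum to 100)."""
    p = Z.shape[1]
    if p > _MAX_LMG_FACTORS:
        raise ValidationError(
            f"LMG enumeration supports at most {_MAX_LMG_FACTORS} factors"
        )
    cache: dict = {}
    full_r2 = _subset_r2(y, Z, tuple(range(p)), cache)
    if full_r2 <= 0:
        warnings.warn("R^2 is zero: all factor contributions set to 0")
        return {n: 0.0 for n in names}
    shares = np.zeros(p)
    perms = list(permutations(range(p)))
    for perm in perms:
        so_far: tuple[int, ...] = ()
        prev = 0.0
        for idx in perm:
            cols = tuple(sorted(so_far + (idx,)))
            r2 = _subset_r2(y, Z, cols, cache)
            shares[idx] += r2 - prev
            prev = r2
            so_far = so_far + (idx,)
    shares /= len(perms)
    pct = 100.0 * shares / full_r2
    return {n: float(pct[i]) for i, n in enumerate(names)}


def factor_contributions(fit: ScoreRegression, scores: Sequence[float],
                         exog: ExogenousTable,
                         score_years: Sequence[int] | None = None
                         ) -> dict[str, float]:
    """Recompute LMG relative-importance percentages for a fitted regression."""
    y, Z = _design(scores, exog, score_years)
    if tuple(exog.factor_names) != fit.factor_names:
        raise ValidationError("factor names do not match the fitted regression")
    return _lmg_contributions(y, Z, fit.factor_names)


def bootstrap_regression(scores: Sequence[float], exog: ExogenousTable,
                         B: int = 1000, seed: int = 0,
                         score_years: Sequence[int] | None = None,
                         component_index: int = 1) -> ScoreRegression:
    """Case-resampling bootstrap of the score-on-factors regression.

    Draws B samples of size n with replacement, refits OLS on each, and
    stores the replicate coefficient matrix (factors only, intercept
    excluded).  Rank-deficient replicates are redrawn, up to 10*B attempts.
    """
    if B < 100:
        raise ValidationError("B must be >= 100")
    base = fit_score_regression(scores, exog, score_years=score_years,
                                component_index=component_index)
    y, Z = _design(scores, exog, score_years)
    n = len(y)
    p = Z.shape[1] + 1
    # standardize factors for the replicate solves (pure reparametrization;
    # keeps the normal equations well-conditioned for ill-scaled factors)
    z_mean = Z.mean(axis=0)
    z_scale = Z.std(axis=0)
    z_scale = np.where(z_scale > 0, z_scale, 1.0)
    X = np.column_stack([np.ones(n), (Z - z_mean) / z_scale])
    rng = np.random.default_rng(seed)
    coefs = np.empty((B, p))
    filled = 0
    attempts = 0
    while filled < B:
        if attempts >= 10 * B:
            raise FitError(
                "bootstrap: too many rank-deficient replicates"
            )
        want = B - filled
        idx = rng.integers(0, n, size=(want, n))
        Xb = X[idx]                      # want x n x p
        yb = y[idx]                      # want x n
        G = np.einsum("bij,bik->bjk", Xb, Xb)
        h = np.einsum("bij,bi->bj", Xb, yb)
        ok = np.linalg.matrix_rank(G) == p
        good = np.flatnonzero(ok)
        if len(good):
            coefs[filled:filled + len(good)] = np.linalg.solve(
                G[good], h[good][..., None]
            )[..., 0]
            filled += len(good)
        attempts += want
    return replace(base, bootstrap_coefficients=coefs[:, 1:] / z_scale)


def bootstrap_percentile_interval(fit: ScoreRegression, factor: str,
                                  level: float = 0.95) -> tuple[float, float]:
    """Percentile confidence interval for one factor's coefficient."""
    if fit.bootstrap_coefficients is None:
        raise ValidationError("fit has no bootstrap replicates")
    j = fit.factor_names.index(factor)
    col = fit.bootstrap_coefficients[:, j]
    lo = (1 - level) / 2
    return (float(np.quantile(col, lo)), float(np.quantile(col, 1 - lo)))


def forecast_scores_exog(fit: ScoreRegression,
                         future_exog: ExogenousTable) -> pd.Series:
    """Predicted scores alpha + sum_i gamma_i z_it for each future year."""
    missing = [n for n in fit.factor_names
               if n not in future_exog.factor_names]
    if missing:
        raise ValidationError(
            f"future exogenous table missing factor {missing[0]!r}"
        )
    values = fit.predict(future_exog.data)
    return pd.Series(values, index=future_exog.data.index, name="score_hat")
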