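"""Lee-Carter mortality model estimated by singular value decomposition.

The model is log m_{x,t} = a_x + b_x k_t + eps_{x,t}: a_x is the mean log
rate of age group x over the fitting years, b_x the age-specific
sensitivity to the common period index k_t, and (b_x, k_t) the leading
singular pair of the centered log-rate matrix.  Identification follows the
classical convention sum(b_x) = 1, sum(k_t) = 0.  The joint sign of the
pair is chosen so that k_t correlates positively with the yearly mean of
the centered log rates ("k_t falls => overall mortality falls" whenever
most b_x are positive); when the data put negative loadings on most ages,
that is reported as estimated, never silently flipped.

No second-stage re-estimation of k_t against observed death counts is
performed: the package works with rates only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .io_mortality import AgeGrid, MortalitySurface, log_rates
from .score_models import forecast_series

__all__ = ["LCFit", "fit_lc", "fitted_log_rates", "forecast_lc"]

_DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class LCFit:
    """Estimated Lee-Carter parameters plus residuals and SVD diagnostics."""

    ages: AgeGrid
    years: np.ndarray
    a_x: np.ndarray
    b_x: np.ndarray
    k_t: np.ndarray
    residuals: np.ndarray
    singular_values: np.ndarray
    degenerate: bool = False

    @property
    def variance_explained_first(self) -> float:
        """Share of centered-matrix variance carried by the leading pair."""
        s2 = self.singular_values ** 2
        total = s2.sum()
        return float(s2[0] / total) if total > 0 else 0.0


def fit_lc(surface: MortalitySurface) -> LCFit:
    """Estimate (a_x, b_x, k_t) by SVD of the centered log-rate matrix."""
    if surface.n_years < 3:
        raise ValidationError("need at least 3 years to fit")
    if surface.n_ages < 2:
        raise ValidationError("need at least 2 age groups to fit")
    L = log_rates(surface)
    a_x = L.mean(axis=1)
    C = L - a_x[:, None]
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    if s[0] < _DEGENERATE_TOL:
        n = surface.n_ages
        return LCFit(
            ages=surface.ages, years=surface.years, a_x=a_x,
            b_x=np.full(n, 1.0 / n), k_t=np.zeros(surface.n_years),
            residuals=C, singular_values=s, degenerate=True,
        )
    b = U[:, 0]
    k = s[0] * Vt[0]
    # sign: k_t tracks the yearly mean of centered log rates
    if np.dot(k, C.mean(axis=0)) < 0:
        b, k = -b, -k
    bsum = b.sum()
    if abs(bsum) > 1e-12:
        b = b / bsum
        k = k * bsum
    k = k - k.mean()
    residuals = C - np.outer(b, k)
    return LCFit(ages=surface.ages, years=surface.years, a_x=a_x, b_x=b,
                 k_t=k, residuals=residuals, singular_values=s)


def fitted_log_rates(fit: LCFit) -> np.ndarray:
    """Reconstruction a_x + b_x k_t (residuals excluded)."""
    return fit.a_x[:, None] + np.outer(fit.b_x, fit.k_t)


def forecast_lc(fit: LCFit, horizon: int,
                kt_forecaster: str = "arima") -> MortalitySurface:
    """Extrapolate k_t and return forecast rates exp(a_x + b_x k_hat).

    The returned surface covers exactly the ``horizon`` years after the
    fitting window.  A degenerate (time-constant) fit yields constant
    mortality exp(a_x) with a warning.
    """
    horizon = int(horizon)
    if horizon < 1:
        raise ValidationError("horizon must be >= 1")
    future_years = np.arange(fit.years[-1] + 1, fit.years[-1] + 1 + horizon)
    if fit.degenerate:
        warnings.warn("degenerate Lee-Carter fit: forecasting constant rates",
                      stacklevel=2)
        rates = np.tile(np.exp(fit.a_x)[:, None], (1, horizon))
        return MortalitySurface(fit.ages, future_years, rates)
    k_hat = forecast_series(kt_forecaster, fit.k_t, horizon).point
    logm = fit.a_x[:, None] + np.outer(fit.b_x, k_hat)
    return MortalitySurface(fit.ages, future_years, np.exp(logm))
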