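"""Functional data model for mortality curves (Hyndman-Ullah style).

Each year's log-rate curve over age is decomposed as

    log m(x, t) = mu(x) + sum_k beta_k(x) kappa_{k,t} + eps(x, t)

with mu the pointwise mean curve, beta_k orthonormal functional principal
component loadings and kappa_{k,t} uncorrelated scores ordered by explained
variance.  Curves may first be projected onto a smoothing basis (B-splines,
Fourier, natural cubic splines) evaluated at the age-group midpoints; the
``data_driven`` regime skips smoothing and takes the principal components
of the raw curves.

The eigen-decomposition is computed via SVD of the centered data matrix for
numerical stability; eigenvalues are squared singular values divided by
(n_years - 1).  Loading signs are fixed so every loading column has a
positive sum, which makes outputs reproducible (FPCA signs are otherwise
arbitrary).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import FitError, ValidationError
from .io_mortality import AgeGrid, MortalitySurface, log_rates
from .score_models import forecast_series

__all__ = ["HUFit", "fit_hu", "forecast_hu", "variance_table", "build_basis"]

BASIS_TYPES = ("data_driven", "bspline", "fourier", "cubic_spline")


# -- basis construction ---------------------------------------------------

def _bspline_basis(x: np.ndarray, n_basis: int) -> np.ndarray:
    from scipy.interpolate import BSpline

    if n_basis < 4:
        raise ValidationError("bspline basis needs n_basis >= 4 (cubic)")
    k = 3
    n_interior = n_basis - (k + 1)
    interior = np.linspace(x[0], x[-1], n_interior + 2)[1:-1]
    t = np.r_[[x[0]] * (k + 1), interior, [x[-1]] * (k + 1)]
    return BSpline.design_matrix(x, t, k, extrapolate=False).toarray()


def _fourier_basis(x: np.ndarray, n_basis: int) -> np.ndarray:
    u = (x - x[0]) / (x[-1] - x[0])
    cols = [np.ones_like(u)]
    j = 1
    while len(cols) < n_basis:
        cols.append(np.sin(2 * np.pi * j * u))
        if len(cols) < n_basis:
            cols.append(np.cos(2 * np.pi * j * u))
        j += 1
    return np.column_stack(cols)


def _natural_cubic_basis(x: np.ndarray, n_basis: int) -> np.ndarray:
    """Natural cubic spline basis with K = n_basis knots (1, x, N_3..N_K)."""
    if n_basis < 3:
        raise ValidationError("cubic_spline basis needs n_basis >= 3")
    knots = np.linspace(x[0], x[-1], n_basis)

    def d(k: int) -> np.ndarray:
        num = (np.maximum(x - knots[k], 0.0) ** 3
               - np.maximum(x - knots[-1], 0.0) ** 3)
        return num / (knots[-1] - knots[k])

    cols = [np.ones_like(x), x]
    d_last = d(n_basis - 2)
    for k in range(n_basis - 2):
        cols.append(d(k) - d_last)
    return np.column_stack(cols[:n_basis])


def build_basis(midpoints: np.ndarray, basis_type: str,
                n_basis: int) -> np.ndarray:
    """Evaluate a smoothing basis at the age-group midpoints."""
    x = np.asarray(midpoints, dtype=float)
    if n_basis > len(x):
        raise ValidationError(
            f"n_basis={n_basis} exceeds the {len(x)} age points"
        )
    if basis_type == "bspline":
        return _bspline_basis(x, n_basis)
    if basis_type == "fourier":
        return _fourier_basis(x, n_basis)
    if basis_type == "cubic_spline":
        return _natural_cubic_basis(x, n_basis)
    raise ValidationError(f"unknown basis type {basis_type!r}")


# -- model ---------------------------------------------------------------

@dataclass(frozen=True)
class HUFit:
    """Fitted functional data model for a mortality surface."""

    ages: AgeGrid
    years: np.ndarray
    mu_x: np.ndarray
    loadings: np.ndarray        # n_ages x K, orthonormal columns
    scores: np.ndarray          # K x n_years, rows uncorrelated
    K: int
    basis_type: str
    n_basis: int | None
    variance_explained: np.ndarray   # length K, proportions of total
    eigenvalues: np.ndarray          # all positive eigenvalues
    residuals: np.ndarray            # raw log rates minus reconstruction

    def fitted_log(self) -> np.ndarray:
        """mu(x) + sum_k beta_k(x) kappa_{k,t}."""
        return self.mu_x[:, None] + self.loadings @ self.scores

    def fitted_rates(self) -> np.ndarray:
        return np.exp(self.fitted_log())


def fit_hu(surface: MortalitySurface, K: int = 3,
           basis_type: str = "data_driven",
           n_basis: int | None = None) -> HUFit:
    """Fit mean function + K functional principal components.

    For the non-data-driven regimes the log-rate curves are first projected
    (unweighted least squares) onto ``n_basis`` basis functions evaluated at
    the age midpoints; ``n_basis`` defaults to the number of age points,
    which makes the projection an interpolation and the four regimes agree.
    """
    if basis_type not in BASIS_TYPES:
        raise ValidationError(f"unknown basis type {basis_type!r}")
    K = int(K)
    kmax = min(surface.n_ages, surface.n_years - 1)
    if not 1 <= K <= kmax:
        raise ValidationError(f"K must be in [1, {kmax}], got {K}")
    L = log_rates(surface)
    if basis_type == "data_driven":
        smoothed = L
        n_basis = None
    else:
        if n_basis is None:
            n_basis = surface.n_ages
        if K > n_basis:
            raise ValidationError(f"K={K} exceeds n_basis={n_basis}")
        B = build_basis(surface.ages.midpoints, basis_type, n_basis)
        coefs, *_ = np.linalg.lstsq(B, L, rcond=None)
        smoothed = B @ coefs
    mu = smoothed.mean(axis=1)
    C = smoothed - mu[:, None]
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    eigvals = s ** 2 / max(surface.n_years - 1, 1)
    pos = eigvals > max(eigvals[0], 1.0) * 1e-15
    eigvals_pos = eigvals[pos]
    total = eigvals_pos.sum()
    loadings = U[:, :K].copy()
    scores = (s[:K, None] * Vt[:K]).copy()
    for k in range(K):
        if loadings[:, k].sum() < 0:
            loadings[:, k] *= -1
            scores[k] *= -1
    var_exp = (eigvals[:K] / total) if total > 0 else np.zeros(K)
    residuals = L - (mu[:, None] + loadings @ scores)
    return HUFit(
        ages=surface.ages, years=surface.years, mu_x=mu, loadings=loadings,
        scores=scores, K=K, basis_type=basis_type, n_basis=n_basis,
        variance_explained=var_exp, eigenvalues=eigvals_pos,
        residuals=residuals,
    )


def forecast_hu(fit: HUFit, horizon: int,
                score_method: str = "arima") -> MortalitySurface:
    """Forecast each score series independently and rebuild the surface."""
    horizon = int(horizon)
    if horizon < 1:
        raise ValidationError("horizon must be >= 1")
    k_hat = np.empty((fit.K, horizon))
    for k in range(fit.K):
        try:
            k_hat[k] = forecast_series(score_method, fit.scores[k],
                                       horizon).point
        except Exception as exc:
            raise FitError(
                f"score forecaster {score_method!r} failed on component "
                f"{k + 1}: {exc}"
            ) from exc
    logm = fit.mu_x[:, None] + fit.loadings @ k_hat
    future_years = np.arange(fit.years[-1] + 1, fit.years[-1] + 1 + horizon)
    return MortalitySurface(fit.ages, future_years, np.exp(logm))


def variance_table(fit: HUFit) -> list[tuple[int, float]]:
    """(component, percentage of variance explained), non-increasing."""
    return [(k + 1, float(100.0 * v)) for k, v in
            enumerate(fit.variance_explained)]
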