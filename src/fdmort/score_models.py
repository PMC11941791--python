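"""Univariate forecasters for period indices and principal-component scores.

Five methods are provided, all with the same calling convention and all
deterministic given the input series:

- ``arima``: automatic ARIMA — differencing order d chosen by a KPSS
  stationarity test (d in {0,1,2}), (p, q) in [0,3]^2 by minimum AICc,
  drift included when d = 1.
- ``ets``: additive-error exponential smoothing state-space model; the
  trend component (none / additive / damped additive) is chosen by AICc.
  Annual series, so no seasonal component.
- ``lr``: ordinary least squares on the time index.
- ``lr_a``: linear trend plus an ARIMA model (d forced to 0) on the trend
  residuals; the forecast is the sum of both extrapolations.
- ``gam``: a penalized cubic smoothing spline of the time index (smoothing
  level by generalized cross-validation), extrapolated linearly with the
  smooth's end slope.  Linear extension is a deliberate convention:
  penalized splines have no natural extrapolation, and the end-slope rule
  makes the method's long-horizon behaviour explicit.

Series are internally mean-centered before ARIMA/ETS/GAM estimation and the
mean is added back, which makes every method exactly shift-equivariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .exceptions import FitError, ValidationError

__all__ = [
    "ScoreForecast",
    "forecast_arima_auto",
    "forecast_ets",
    "forecast_lr",
    "forecast_lr_a",
    "forecast_gam",
    "forecast_series",
    "SCORE_METHODS",
    "METHOD_ORDER",
]

#: Canonical method ordering, used as the final tie-break in selection.
METHOD_ORDER: tuple[str, ...] = ("arima", "ets", "lr", "lr_a", "gam")


@dataclass(frozen=True)
class ScoreForecast:
    """Point forecasts from one univariate method.

    ``meta`` carries method-specific descriptors: ARIMA order and drift,
    ETS component spec, regression coefficients, and ``n_params`` (used for
    parsimony tie-breaks in model selection).
    """

    method: str
    fitted: np.ndarray
    point: np.ndarray
    interval: tuple[np.ndarray, np.ndarray] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "fitted", np.asarray(self.fitted, float))
        object.__setattr__(self, "point", np.asarray(self.point, float))
        if self.interval is not None:
            lo, hi = self.interval
            lo = np.asarray(lo, float)
            hi = np.asarray(hi, float)
            object.__setattr__(self, "interval", (lo, hi))
            if np.any(lo > self.point + 1e-9) or np.any(hi < self.point - 1e-9):
                raise ValidationError("interval must bracket point forecasts")


def _check_series(y: Sequence[float], min_len: int, method: str) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValidationError(f"{method}: series must be 1-d")
    if len(y) < min_len:
        raise ValidationError(
            f"{method}: need at least {min_len} observations, got {len(y)}"
        )
    if not np.all(np.isfinite(y)):
        raise ValidationError(f"{method}: series contains non-finite values")
    return y


def _check_horizon(horizon: int) -> int:
    horizon = int(horizon)
    if horizon < 1:
        raise ValidationError("horizon must be >= 1")
    return horizon


def _is_constant(y: np.ndarray) -> bool:
    return np.ptp(y) <= 1e-12 * max(1.0, np.max(np.abs(y)))


def _flat(method: str, y: np.ndarray, horizon: int, **meta) -> ScoreForecast:
    c = float(y[-1])
    m = {"constant": True, "n_params": 1}
    m.update(meta)
    return ScoreForecast(method=method, fitted=np.full(len(y), c),
                         point=np.full(horizon, c), meta=m)


# -- ARIMA ----------------------------------------------------------------

def _kpss_d(y: np.ndarray, alpha: float, max_d: int) -> int:
    """Number of differences needed for KPSS level-stationarity."""
    from statsmodels.tsa.stattools import kpss

    z = y.copy()
    for d in range(max_d + 1):
        if _is_constant(z):
            return d
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                _, pval, *_ = kpss(z, regression="c", nlags="auto")
            except (ValueError, OverflowError):
                return d
        if pval >= alpha:
            return d
        z = np.diff(z)
    return max_d


def forecast_arima_auto(series: Sequence[float], horizon: int, *,
                        d: int | None = None, max_p: int = 3, max_q: int = 3,
                        max_d: int = 2,
                        stationarity_alpha: float = 0.05) -> ScoreForecast:
    """Automatic ARIMA: KPSS-selected d, AICc-selected (p, q), drift if d=1.

    If the d-times differenced series is (numerically) constant the process
    is a deterministic polynomial of degree d and the exact polynomial
    extrapolation is returned — this is what any ARIMA with zero innovation
    variance degenerates to, and it avoids an ill-posed likelihood.
    """
    y = _check_series(series, 5, "arima")
    horizon = _check_horizon(horizon)
    if _is_constant(y):
        return _flat("arima", y, horizon, order=(0, 0, 0), drift=False)
    if d is None:
        d = _kpss_d(y, stationarity_alpha, max_d)
    d = int(d)

    diffed = y.copy()
    for _ in range(d):
        diffed = np.diff(diffed)
    if d > 0 and _is_constant(diffed):
        t = np.arange(len(y), dtype=float)
        coef = np.polyfit(t, y, deg=d)
        tf = np.arange(len(y), len(y) + horizon, dtype=float)
        meta = {"order": (0, d, 0), "drift": d == 1, "deterministic": True,
                "n_params": d + 1}
        if d == 1:
            meta["drift_estimate"] = float(coef[0])
        return ScoreForecast(method="arima", fitted=np.polyval(coef, t),
                             point=np.polyval(coef, tf), meta=meta)

    from statsmodels.tsa.arima.model import ARIMA

    mu = y.mean()
    yc = y - mu
    trend = "c" if d == 0 else ("t" if d == 1 else "n")
    best = None
    last_err: Exception | None = None
    for p in range(max_p + 1):
        for q in range(max_q + 1):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = ARIMA(yc, order=(p, d, q), trend=trend,
                                concentrate_scale=True).fit(
                                    method_kwargs={"maxiter": 30})
                aicc = float(res.aicc)
                if not np.isfinite(aicc):
                    continue
                # guard against likelihood blow-ups: a stochastic series
                # whose ARMA fit claims a near-zero innovation variance is
                # a degenerate optimum (deterministic series never reach
                # this loop), and its forecasts are untrustworthy
                if float(res.mse) < 1e-8 * np.var(diffed):
                    continue
                point_try = np.asarray(res.get_forecast(1).predicted_mean)
                if abs(point_try[0] - yc[-1]) > 10 * max(np.ptp(yc), 1e-12):
                    continue
                key = (aicc, p + q)
                if best is None or key < best[0]:
                    best = (key, (p, q), res)
            except Exception as exc:  # statsmodels raises many types here
                last_err = exc
    if best is None:
        raise FitError(f"arima: all candidate fits failed (last: {last_err})")
    _, (p, q), res = best
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fc = res.get_forecast(horizon)
        point = np.asarray(fc.predicted_mean) + mu
        ci = np.asarray(fc.conf_int(alpha=0.05))
    meta = {"order": (p, d, q), "drift": d == 1, "aicc": float(res.aicc),
            "n_params": p + q + (0 if trend == "n" else 1) + 1}
    if d == 1 and trend == "t":
        meta["drift_estimate"] = float(np.asarray(res.params)[0])
    return ScoreForecast(method="arima", fitted=np.asarray(res.fittedvalues) + mu,
                         point=point,
                         interval=(ci[:, 0] + mu, ci[:, 1] + mu), meta=meta)


# -- ETS ------------------------------------------------------------------

def forecast_ets(series: Sequence[float], horizon: int) -> ScoreForecast:
    """Additive-error ETS; trend spec (none/additive/damped) chosen by AICc."""
    y = _check_series(series, 4, "ets")
    horizon = _check_horizon(horizon)
    if _is_constant(y):
        return _flat("ets", y, horizon, trend=None)

    # A numerically exact linear series makes the innovation variance
    # collapse; the additive-trend model then degenerates to the line.
    t = np.arange(len(y), dtype=float)
    slope, intercept = np.polyfit(t, y, 1)
    line = intercept + slope * t
    if np.max(np.abs(y - line)) <= 1e-10 * max(1.0, np.ptp(y)):
        tf = np.arange(len(y), len(y) + horizon, dtype=float)
        return ScoreForecast(
            method="ets", fitted=line, point=intercept + slope * tf,
            meta={"trend": "add", "damped": False, "degenerate_linear": True,
                  "n_params": 4},
        )

    from statsmodels.tsa.exponential_smoothing.ets import ETSModel

    mu = y.mean()
    yc = y - mu
    candidates = [
        (None, False, 2),          # level only: alpha + level state
        ("add", False, 4),         # + beta, trend state
        ("add", True, 5),          # + damping
    ]
    best = None
    last_err: Exception | None = None
    for trend, damped, n_params in candidates:
        if trend is None and damped:
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = ETSModel(yc, error="add", trend=trend,
                                 damped_trend=damped)
                res = model.fit(disp=False)
            aicc = float(res.aicc)
            if not np.isfinite(aicc):
                continue
            key = (aicc, n_params)
            if best is None or key < best[0]:
                best = (key, trend, damped, n_params, res)
        except Exception as exc:
            last_err = exc
    if best is None:
        raise FitError(f"ets: all candidate fits failed (last: {last_err})")
    _, trend, damped, n_params, res = best
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        point = np.asarray(res.forecast(horizon)) + mu
    return ScoreForecast(
        method="ets", fitted=np.asarray(res.fittedvalues) + mu, point=point,
        meta={"trend": trend, "damped": damped, "aicc": float(res.aicc),
              "n_params": n_params},
    )


# -- linear regression ----------------------------------------------------

def forecast_lr(series: Sequence[float], horizon: int) -> ScoreForecast:
    """OLS of the value on the time index 1..n, extrapolated to n+horizon."""
    y = _check_series(series, 3, "lr")
    horizon = _check_horizon(horizon)
    t = np.arange(1, len(y) + 1, dtype=float)
    slope, intercept = np.polyfit(t, y, 1)
    tf = np.arange(len(y) + 1, len(y) + horizon + 1, dtype=float)
    return ScoreForecast(
        method="lr", fitted=intercept + slope * t,
        point=intercept + slope * tf,
        meta={"slope": float(slope), "intercept": float(intercept),
              "n_params": 2},
    )


def forecast_lr_a(series: Sequence[float], horizon: int) -> ScoreForecast:
    """Linear trend plus ARIMA(p,0,q) on the trend residuals.

    Differencing is disabled for the residual model: the trend is already
    removed, and differencing a detrended series would double-count it.
    """
    y = _check_series(series, 6, "lr_a")
    horizon = _check_horizon(horizon)
    base = forecast_lr(y, horizon)
    resid = y - base.fitted
    if np.max(np.abs(resid)) <= 1e-12 * max(1.0, np.ptp(y), np.max(np.abs(y))):
        return ScoreForecast(method="lr_a", fitted=base.fitted,
                             point=base.point,
                             meta={**base.meta, "resid_order": (0, 0, 0),
                                   "n_params": 2})
    resid_fc = forecast_arima_auto(resid, horizon, d=0)
    return ScoreForecast(
        method="lr_a", fitted=base.fitted + resid_fc.fitted,
        point=base.point + resid_fc.point,
        meta={"slope": base.meta["slope"], "intercept": base.meta["intercept"],
              "resid_order": resid_fc.meta.get("order"),
              "n_params": 2 + resid_fc.meta.get("n_params", 1)},
    )


# -- GAM ------------------------------------------------------------------

def forecast_gam(series: Sequence[float], horizon: int) -> ScoreForecast:
    """Penalized cubic smoothing spline of the time index (GCV smoothing).

    Beyond the data range the smooth is extended linearly with its slope at
    the last observation.  On curved series this makes long-horizon
    forecasts drift away from the curvature — a documented property of
    spline smoothers used for extrapolation.
    """
    y = _check_series(series, 8, "gam")
    horizon = _check_horizon(horizon)
    if _is_constant(y):
        return _flat("gam", y, horizon)
    t = np.arange(1, len(y) + 1, dtype=float)
    mu = y.mean()
    try:
        spl = make_smoothing_spline(t, y - mu)
    except Exception as exc:
        raise FitError(f"gam: smoothing spline failed: {exc}") from exc
    fitted = spl(t) + mu
    end_value = float(spl(t[-1]) + mu)
    end_slope = float(spl.derivative()(t[-1]))
    h = np.arange(1, horizon + 1, dtype=float)
    return ScoreForecast(
        method="gam", fitted=fitted, point=end_value + end_slope * h,
        meta={"end_slope": end_slope, "n_params": 4},
    )


SCORE_METHODS: dict[str, Callable[..., ScoreForecast]] = {
    "arima": forecast_arima_auto,
    "ets": forecast_ets,
    "lr": forecast_lr,
    "lr_a": forecast_lr_a,
    "gam": forecast_gam,
}


def forecast_series(method: str, series: Sequence[float],
                    horizon: int) -> ScoreForecast:
    """Dispatch to one of the five named forecasters."""
    try:
        fn = SCORE_METHODS[method]
    except KeyError:
        raise ValidationError(
            f"unknown score method {method!r}; choose from {METHOD_ORDER}"
        ) from None
    return fn(series, horizon)
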