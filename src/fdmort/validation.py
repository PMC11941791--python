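"""Train/test splitting, APE/MAPE accuracy metrics and forecaster selection.

Accuracy follows the absolute-percentage-error convention:

    APE  = |m - m_hat| / m * 100
    MAPE = mean of APEs

Per-age MAPEs average over test years; the overall figure is the unweighted
mean over age groups (the "Mean" row of a standard accuracy table).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .exceptions import FitError, ValidationError
from .io_mortality import MortalitySurface
from .score_models import METHOD_ORDER, ScoreForecast, forecast_series

__all__ = [
    "AccuracyReport",
    "split_surface",
    "ape",
    "mape",
    "evaluate_forecast",
    "select_best_method",
    "SelectionResult",
]


@dataclass(frozen=True)
class AccuracyReport:
    """APE matrix with row/column MAPE marginals."""

    row_labels: tuple[str, ...]
    years: np.ndarray
    ape: np.ndarray            # n_rows x n_years
    mape_by_age: np.ndarray    # row means
    mape_by_year: np.ndarray   # column means
    overall: float             # unweighted mean of per-age MAPEs

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.ape, index=list(self.row_labels),
                          columns=list(self.years))
        df["MAPE"] = self.mape_by_age
        mean_row = np.append(self.mape_by_year, self.overall)
        df.loc["Mean"] = mean_row
        return df


def split_surface(surface: MortalitySurface,
                  last_train_year: int) -> tuple[MortalitySurface,
                                                 MortalitySurface]:
    """Split into a training frame (..last_train_year] and a test frame."""
    y = int(last_train_year)
    years = surface.years
    if y < years[0] or y >= years[-1]:
        raise ValidationError(
            f"last_train_year {y} must lie strictly inside "
            f"[{years[0]}, {years[-1]})"
        )
    cut = int(np.searchsorted(years, y, side="right"))
    train = MortalitySurface(surface.ages, years[:cut], surface.rates[:, :cut])
    test = MortalitySurface(surface.ages, years[cut:], surface.rates[:, cut:])
    return train, test


def ape(actual: float, forecast: float) -> float:
    """Absolute percentage error of a single forecast."""
    actual = float(actual)
    if actual <= 0:
        raise ValidationError("APE needs a positive actual value")
    return abs(actual - float(forecast)) / actual * 100.0


def _ape_matrix(actual: np.ndarray, forecast: np.ndarray) -> np.ndarray:
    actual = np.asarray(actual, dtype=float)
    forecast = np.asarray(forecast, dtype=float)
    if actual.shape != forecast.shape:
        raise ValidationError(
            f"shape mismatch: {actual.shape} vs {forecast.shape}"
        )
    if np.any(actual <= 0):
        raise ValidationError("APE needs positive actual values")
    return np.abs(actual - forecast) / actual * 100.0


def mape(actuals: Sequence[float], forecasts: Sequence[float]) -> float:
    """Mean absolute percentage error over paired series."""
    a = np.atleast_1d(np.asarray(actuals, dtype=float))
    f = np.atleast_1d(np.asarray(forecasts, dtype=float))
    if a.shape != f.shape or a.size == 0:
        raise ValidationError("actuals and forecasts must have equal length >= 1")
    return float(_ape_matrix(a, f).mean())


def evaluate_forecast(test: MortalitySurface,
                      forecast: MortalitySurface) -> AccuracyReport:
    """Full APE matrix and MAPE marginals for a forecast surface."""
    if tuple(test.ages.labels) != tuple(forecast.ages.labels):
        raise ValidationError("age grids of test and forecast differ")
    if not np.array_equal(test.years, forecast.years):
        raise ValidationError("year ranges of test and forecast differ")
    ape_m = _ape_matrix(test.rates, forecast.rates)
    by_age = ape_m.mean(axis=1)
    by_year = ape_m.mean(axis=0)
    return AccuracyReport(
        row_labels=tuple(test.ages.labels), years=test.years.copy(),
        ape=ape_m, mape_by_age=by_age, mape_by_year=by_year,
        overall=float(by_age.mean()),
    )


class SelectionResult(NamedTuple):
    method: str
    report: AccuracyReport
    candidate_mape: dict[str, float]
    forecasts: dict[str, ScoreForecast]


_TIE_TOL = 1e-8


def select_best_method(series: Sequence[float],
                       candidates: Iterable[str],
                       last_train_index: int,
                       label: str = "series") -> SelectionResult:
    """Pick the candidate with the lowest mean APE on a validation window.

    Each candidate is fit on ``series[:last_train_index]`` and scored on
    the remaining points.  Mean APEs within 1e-8 of the minimum are treated
    as tied; ties go to the method with fewer parameters, then to the fixed
    method order (arima, ets, lr, lr_a, gam).
    """
    y = np.asarray(series, dtype=float)
    cands = list(candidates)
    if len(cands) < 2:
        raise ValidationError("need at least 2 candidate methods")
    lti = int(last_train_index)
    if not 1 <= lti < len(y):
        raise ValidationError("validation window must contain >= 1 point")
    if np.any(y[lti:] <= 0):
        raise ValidationError("APE selection needs positive validation values")
    train, valid = y[:lti], y[lti:]
    horizon = len(valid)
    scores: dict[str, float] = {}
    fcs: dict[str, ScoreForecast] = {}
    failures: dict[str, str] = {}
    for m in cands:
        try:
            fc = forecast_series(m, train, horizon)
            scores[m] = mape(valid, fc.point)
            fcs[m] = fc
        except Exception as exc:
            failures[m] = str(exc)
    if not scores:
        detail = "; ".join(f"{m}: {msg}" for m, msg in failures.items())
        raise FitError(f"all candidate methods failed ({detail})")
    best_score = min(scores.values())
    tied = [m for m, s in scores.items() if s - best_score <= _TIE_TOL]

    def rank(m: str) -> tuple:
        n_params = fcs[m].meta.get("n_params", np.inf)
        order = METHOD_ORDER.index(m) if m in METHOD_ORDER else len(METHOD_ORDER)
        return (n_params, order)

    winner = min(tied, key=rank)
    ape_row = _ape_matrix(valid, fcs[winner].point)[None, :]
    years = np.arange(lti + 1, len(y) + 1)
    report = AccuracyReport(
        row_labels=(label,), years=years, ape=ape_row,
        mape_by_age=ape_row.mean(axis=1), mape_by_year=ape_row.mean(axis=0),
        overall=float(ape_row.mean()),
    )
    return SelectionResult(method=winner, report=report,
                           candidate_mape=scores, forecasts=fcs)
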