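"""End-to-end forecasting pipeline with child/adult subpopulation split.

The workflow mirrors how national age-specific mortality is best modeled
when child and adult trends differ in shape:

1. level out designated outlier years by log-linear interpolation;
2. split the surface into a child block (default: 0, 1-4, 5-9, 10-14) and
   an adolescent-adult block (15-19 and older);
3. fit the adult block with the functional data model and forecast its
   scores (optionally from exogenous factors via score regression);
4. model each child group separately, selecting among ARIMA, ETS, GAM, LR
   and LR+A by held-out mean APE;
5. merge forecasts, score them on the test frame, and emit reports.

Child groups are modeled on the log-rate scale for the LR/LR+A/GAM family
(consistent with the log-bilinear structure of mortality); ARIMA and ETS
fit the raw rates, as is standard practice for those models.  The scale
used per method is recorded in the run log.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .exceptions import FitError, ValidationError
from .exog_fpcr import (
    ScoreRegression,
    bootstrap_regression,
    fit_score_regression,
    forecast_scores_exog,
)
from .hu_fpca import HUFit, fit_hu, forecast_hu, variance_table
from .io_mortality import (
    ExogenousTable,
    MortalitySurface,
    read_exogenous,
    read_rates,
    replace_years_by_interpolation,
    write_rates,
)
from .score_models import METHOD_ORDER, ScoreForecast, forecast_series
from .validation import AccuracyReport, evaluate_forecast, mape, split_surface

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "compare_whole_vs_subpop", "ComparisonResult"]

#: Methods fit on log rates when applied to a single age group's series.
LOG_SCALE_METHODS = frozenset({"lr", "lr_a", "gam"})

_RATE_FLOOR = 1e-12


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    rates_path: str | None = None
    exog_path: str | None = None
    unit: str = "per_person"
    outlier_years: tuple[int, ...] = ()
    last_train_year: int | None = None      # default: 10 test years
    horizon: int = 10
    child_groups: tuple[str, ...] = ("0", "1-4", "5-9", "10-14")
    n_components: int = 3
    basis_type: str = "data_driven"
    n_basis: int | None = None
    score_method: str = "arima"
    child_candidates: tuple[str, ...] = METHOD_ORDER
    use_exogenous: bool = False
    bootstrap_b: int = 1000
    seed: int = 0
    refit_on_full: bool = True
    forecast_future: bool = True
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValidationError("horizon must be >= 1")
        unknown = [m for m in self.child_candidates if m not in METHOD_ORDER]
        if unknown:
            raise ValidationError(f"unknown child candidate {unknown[0]!r}")


@dataclass
class PipelineResult:
    """All artifacts of one pipeline run."""

    config: PipelineConfig
    fitted_train: MortalitySurface
    forecast_test: MortalitySurface
    forecast_future: MortalitySurface | None
    accuracy_train: AccuracyReport
    accuracy_test: AccuracyReport
    hu_fit: HUFit
    child_selections: dict[str, dict]
    regressions: list[ScoreRegression]
    run_log: dict


def _forecast_single_group(series: np.ndarray, method: str,
                           horizon: int) -> tuple[np.ndarray, np.ndarray]:
    """(fitted, point) on the rate scale, honoring the per-method scale rule."""
    if method in LOG_SCALE_METHODS:
        fc = forecast_series(method, np.log(series), horizon)
        return np.exp(fc.fitted), np.exp(fc.point)
    fc = forecast_series(method, series, horizon)
    return (np.maximum(fc.fitted, _RATE_FLOOR),
            np.maximum(fc.point, _RATE_FLOOR))


def _select_child_method(series: np.ndarray, candidates: Sequence[str],
                         n_train: int) -> tuple[str, dict[str, float]]:
    """Lowest mean APE on the held-out window; ties to fewer parameters."""
    train, valid = series[:n_train], series[n_train:]
    scores: dict[str, float] = {}
    n_params: dict[str, float] = {}
    failures: dict[str, str] = {}
    for m in candidates:
        try:
            if m in LOG_SCALE_METHODS:
                fc = forecast_series(m, np.log(train), len(valid))
                point = np.exp(fc.point)
            else:
                fc = forecast_series(m, train, len(valid))
                point = np.maximum(fc.point, _RATE_FLOOR)
            scores[m] = mape(valid, point)
            n_params[m] = fc.meta.get("n_params", np.inf)
        except Exception as exc:
            failures[m] = str(exc)
    if not scores:
        detail = "; ".join(f"{m}: {msg}" for m, msg in failures.items())
        raise FitError(f"all child candidates failed ({detail})")
    best = min(scores.values())
    tied = [m for m, s in scores.items() if s - best <= 1e-8]
    winner = min(tied, key=lambda m: (n_params[m], METHOD_ORDER.index(m)))
    return winner, scores


def _merge_surfaces(order: Sequence[str], parts: dict[str, np.ndarray],
                    template: MortalitySurface,
                    years: np.ndarray) -> MortalitySurface:
    rates = np.vstack([parts[lab] for lab in order])
    grid = template.ages.subset(order)
    return MortalitySurface(grid, years, rates)


def _adult_score_forecasts(hu: HUFit, horizon: int, config: PipelineConfig,
                           exog: ExogenousTable | None,
                           future_years: np.ndarray,
                           regressions: list[ScoreRegression],
                           log: dict) -> np.ndarray:
    """K x horizon score forecasts, exogenous when configured and possible."""
    want_exog = config.use_exogenous and exog is not None
    if want_exog and all(int(y) in set(exog.years) for y in future_years):
        future_tab = exog.subset_years(future_years)
        k_hat = np.vstack([
            forecast_scores_exog(reg, future_tab).to_numpy()
            for reg in regressions
        ])
        log["adult_score_source"] = "exogenous_regression"
        return k_hat
    k_hat = np.empty((hu.K, horizon))
    for k in range(hu.K):
        try:
            k_hat[k] = forecast_series(config.score_method, hu.scores[k],
                                       horizon).point
        except Exception as exc:
            raise FitError(
                f"adult score forecast failed on component {k + 1}: {exc}"
            ) from exc
    log["adult_score_source"] = config.score_method
    return k_hat


def run_pipeline(config: PipelineConfig,
                 surface: MortalitySurface | None = None,
                 exog: ExogenousTable | None = None) -> PipelineResult:
    """Run the split child/adult forecasting workflow end to end."""
    if surface is None:
        if config.rates_path is None:
            raise ValidationError("no surface given and no rates_path configured")
        surface = read_rates(config.rates_path, unit=config.unit)
    if exog is None and config.exog_path is not None:
        exog = read_exogenous(config.exog_path)
    if config.use_exogenous and exog is None:
        raise ValidationError("use_exogenous=True requires an exogenous table")

    run_log: dict = {"seed": config.seed, "stages": []}

    if config.outlier_years:
        surface = replace_years_by_interpolation(surface, config.outlier_years)
        run_log["stages"].append(
            {"stage": "outlier_interpolation",
             "years": [int(y) for y in config.outlier_years]}
        )

    last_train = (config.last_train_year if config.last_train_year is not None
                  else int(surface.years[max(len(surface.years) - 11, 0)]))
    train, test = split_surface(surface, last_train)
    n_train = train.n_years
    run_log["last_train_year"] = int(last_train)

    child_labels = [l for l in surface.ages.labels if l in set(config.child_groups)]
    adult_labels = [l for l in surface.ages.labels if l not in set(config.child_groups)]
    missing = set(config.child_groups) - set(surface.ages.labels)
    if missing:
        raise ValidationError(f"child group {sorted(missing)[0]!r} not in surface")
    if len(adult_labels) < 2:
        raise ValidationError("adult subpopulation needs at least 2 age groups")

    # ---- adult block: functional data model --------------------------
    adult_train = train.subset_ages(adult_labels)
    K = min(config.n_components, adult_train.n_ages, adult_train.n_years - 1)
    try:
        hu = fit_hu(adult_train, K=K, basis_type=config.basis_type,
                    n_basis=config.n_basis)
    except Exception as exc:
        raise FitError(f"stage adult_hu_fit failed: {exc}") from exc
    run_log["variance_table"] = variance_table(hu)

    regressions: list[ScoreRegression] = []
    if config.use_exogenous:
        train_exog = exog.subset_years(train.years)
        for k in range(hu.K):
            reg = bootstrap_regression(
                hu.scores[k], train_exog, B=config.bootstrap_b,
                seed=config.seed + k, component_index=k + 1,
            )
            regressions.append(reg)
        run_log["regressions"] = [
            {"component": r.component_index, "r_squared": r.r_squared,
             "coefficients": r.coefficients, "p_values": r.p_values,
             "contributions": r.contributions}
            for r in regressions
        ]

    h_test = test.n_years
    k_hat_test = _adult_score_forecasts(hu, h_test, config, exog,
                                        test.years, regressions, run_log)
    adult_test_rates = np.exp(hu.mu_x[:, None] + hu.loadings @ k_hat_test)
    adult_fitted = hu.fitted_rates()

    # ---- child block: per-group univariate selection -----------------
    child_selections: dict[str, dict] = {}
    child_test_parts: dict[str, np.ndarray] = {}
    child_fitted_parts: dict[str, np.ndarray] = {}
    child_surface = surface.subset_ages(child_labels) if child_labels else None
    for i, lab in enumerate(child_labels):
        series = child_surface.rates[i]
        try:
            winner, cand_mape = _select_child_method(
                series, config.child_candidates, n_train
            )
            fitted, point = _forecast_single_group(series[:n_train], winner,
                                                   h_test)
        except Exception as exc:
            raise FitError(f"stage child_selection failed for age group "
                           f"{lab!r}: {exc}") from exc
        child_selections[lab] = {"method": winner, "candidate_mape": cand_mape,
                                 "scale": "log" if winner in LOG_SCALE_METHODS
                                 else "rate"}
        child_test_parts[lab] = point
        child_fitted_parts[lab] = fitted
    run_log["child_selections"] = child_selections

    # ---- merge, score -------------------------------------------------
    order = list(surface.ages.labels)
    parts_test = dict(child_test_parts)
    parts_fit = dict(child_fitted_parts)
    for i, lab in enumerate(adult_labels):
        parts_test[lab] = adult_test_rates[i]
        parts_fit[lab] = adult_fitted[i]
    forecast_test = _merge_surfaces(order, parts_test, surface, test.years)
    fitted_train = _merge_surfaces(order, parts_fit, surface, train.years)
    accuracy_test = evaluate_forecast(test, forecast_test)
    accuracy_train = evaluate_forecast(train, fitted_train)
    run_log["overall_test_mape"] = accuracy_test.overall
    run_log["overall_train_mape"] = accuracy_train.overall

    # ---- forecast beyond the data ------------------------------------
    forecast_future = None
    if config.forecast_future:
        h = config.horizon
        future_years = np.arange(surface.years[-1] + 1,
                                 surface.years[-1] + 1 + h)
        adult_full = (surface.subset_ages(adult_labels) if config.refit_on_full
                      else adult_train)
        hu_full = (fit_hu(adult_full, K=min(K, adult_full.n_years - 1),
                          basis_type=config.basis_type, n_basis=config.n_basis)
                   if config.refit_on_full else hu)
        future_regs: list[ScoreRegression] = []
        if config.use_exogenous and all(int(y) in set(exog.years)
                                        for y in future_years):
            full_exog = exog.subset_years(adult_full.years)
            future_regs = [
                fit_score_regression(hu_full.scores[k], full_exog,
                                     component_index=k + 1)
                for k in range(hu_full.K)
            ]
        k_hat_f = _adult_score_forecasts(hu_full, h, config, exog,
                                         future_years, future_regs, run_log)
        adult_future = np.exp(hu_full.mu_x[:, None] + hu_full.loadings @ k_hat_f)
        parts_future: dict[str, np.ndarray] = {}
        for i, lab in enumerate(adult_labels):
            parts_future[lab] = adult_future[i]
        for i, lab in enumerate(child_labels):
            series = (child_surface.rates[i] if config.refit_on_full
                      else child_surface.rates[i, :n_train])
            method = child_selections[lab]["method"]
            _, point = _forecast_single_group(series, method, h)
            parts_future[lab] = point
        forecast_future = _merge_surfaces(order, parts_future, surface,
                                          future_years)

    result = PipelineResult(
        config=config, fitted_train=fitted_train, forecast_test=forecast_test,
        forecast_future=forecast_future, accuracy_train=accuracy_train,
        accuracy_test=accuracy_test, hu_fit=hu,
        child_selections=child_selections, regressions=regressions,
        run_log=run_log,
    )
    if config.outdir is not None:
        _write_outputs(result, Path(config.outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    if result.forecast_future is not None:
        write_rates(result.forecast_future, outdir / "forecast.csv",
                    unit=cfg.unit)
    write_rates(result.forecast_test, outdir / "forecast_test.csv",
                unit=cfg.unit)
    result.accuracy_train.to_frame().to_csv(outdir / "accuracy_train.csv",
                                            float_format="%.6f")
    result.accuracy_test.to_frame().to_csv(outdir / "accuracy_test.csv",
                                           float_format="%.6f")
    with open(outdir / "variance_table.json", "w") as fh:
        json.dump({"variance_explained_pct": result.run_log["variance_table"]},
                  fh, indent=2)
    if result.regressions:
        rows = []
        for reg in result.regressions:
            for name in reg.factor_names:
                rows.append({
                    "component": reg.component_index, "factor": name,
                    "gamma": reg.coefficients[name],
                    "p_value": reg.p_values[name],
                    "contribution_pct": reg.contributions[name],
                    "r_squared": reg.r_squared,
                })
        pd.DataFrame(rows).to_csv(outdir / "regressions.csv", index=False,
                                  float_format="%.10g")
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(result.run_log, fh, indent=2, default=str)


class ComparisonResult(NamedTuple):
    whole: AccuracyReport
    split: AccuracyReport


def compare_whole_vs_subpop(config: PipelineConfig,
                            surface: MortalitySurface | None = None,
                            exog: ExogenousTable | None = None
                            ) -> ComparisonResult:
    """Score a whole-population functional model against the split pipeline.

    Both are run on identical (outlier-leveled) data with identical
    train/test frames, so the two accuracy reports are directly comparable.
    """
    if surface is None:
        if config.rates_path is None:
            raise ValidationError("no surface given and no rates_path configured")
        surface = read_rates(config.rates_path, unit=config.unit)
    if exog is None and config.exog_path is not None:
        exog = read_exogenous(config.exog_path)

    work = surface
    if config.outlier_years:
        work = replace_years_by_interpolation(work, config.outlier_years)
    last_train = (config.last_train_year if config.last_train_year is not None
                  else int(work.years[max(len(work.years) - 11, 0)]))
    train, test = split_surface(work, last_train)
    K = min(config.n_components, train.n_ages, train.n_years - 1)
    hu = fit_hu(train, K=K, basis_type=config.basis_type,
                n_basis=config.n_basis)
    whole_fc = forecast_hu(hu, test.n_years, score_method=config.score_method)
    whole_fc = MortalitySurface(whole_fc.ages, test.years, whole_fc.rates)
    whole_report = evaluate_forecast(test, whole_fc)

    from dataclasses import replace as dc_replace
    sub_cfg = dc_replace(config, forecast_future=False, outdir=None)
    split_report = run_pipeline(sub_cfg, surface=surface,
                                exog=exog).accuracy_test
    return ComparisonResult(whole=whole_report, split=split_report)
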