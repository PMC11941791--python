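"""Synthetic mortality surfaces and exogenous series.

The generators emulate the statistical structure of a post-Soviet national
mortality surface: a log-bilinear age/period decomposition with a nonlinear
global period index (rise in the 1990s, plateau, decline from the late
2000s), linear log-scale declines in the child age groups, pandemic-style
outlier years, and macro covariates with characteristic shapes (GDP growing
then dipping, U-shaped population, flat doctor density).

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io_mortality import (
    AgeGrid,
    ExogenousTable,
    MortalitySurface,
    default_age_grid,
)

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "simulate_lc_surface",
    "simulate_two_subpop",
    "simulate_exogenous",
    "inject_outliers",
    "child_spec",
    "adult_spec",
    "study_scenario",
    "default_baseline_log_rates",
    "default_age_loadings",
]

# Plausible abridged-schedule death rates (per person-year) for a
# middle-income country: high infant mortality, minimum around ages 10-14,
# near-Gompertz rise thereafter.
_BASELINE_RATES: tuple[float, ...] = (
    0.022, 0.0013, 0.00055, 0.00045, 0.0010, 0.0016, 0.0019, 0.0023,
    0.0030, 0.0041, 0.0058, 0.0084, 0.012, 0.018, 0.026, 0.039,
    0.059, 0.091, 0.18,
)

# Relative age sensitivities to the common period index, peaking in early
# childhood, young adulthood (20-24), late middle age (50-54) and old age.
_LOADING_SHAPE: tuple[float, ...] = (
    1.30, 1.60, 1.20, 1.00, 1.10, 1.50, 1.20, 1.00, 0.90, 0.85,
    0.90, 1.20, 0.90, 0.80, 0.75, 0.70, 0.70, 0.80, 1.10,
)


def default_baseline_log_rates(n_ages: int = 19) -> np.ndarray:
    """Baseline log death rates a_x for the standard 19-group grid."""
    if n_ages > len(_BASELINE_RATES):
        raise ValidationError("baseline profile defined for at most 19 groups")
    return np.log(np.array(_BASELINE_RATES[:n_ages]))


def default_age_loadings(n_ages: int = 19) -> np.ndarray:
    """Age loadings b_x normalized to sum to one."""
    if n_ages > len(_LOADING_SHAPE):
        raise ValidationError("loading profile defined for at most 19 groups")
    b = np.array(_LOADING_SHAPE[:n_ages])
    return b / b.sum()


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative log-bilinear specification log m_{x,t} = a_x + b_x k_t + eps.

    ``kt_regime`` selects the shape of the period index:

    - ``"linear"``: k_t a centered line; ``kt_params={"slope": s}``.
    - ``"rw_drift"``: random walk with drift;
      ``kt_params={"drift": mu, "sigma": s}``.
    - ``"piecewise_nonlinear"``: piecewise-linear path with two breakpoints,
      ``kt_params={"breakpoints": (y1, y2), "slopes": (s1, s2, s3)}`` —
      rise, plateau/slow decline, accelerated decline.
    """

    ages: AgeGrid
    years: np.ndarray
    a_x: np.ndarray
    b_x: np.ndarray
    kt_regime: str
    kt_params: Mapping[str, object]
    noise_sigma: float
    seed: int

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        a = np.asarray(self.a_x, dtype=float)
        b = np.asarray(self.b_x, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "a_x", a)
        object.__setattr__(self, "b_x", b)
        object.__setattr__(self, "kt_params", dict(self.kt_params))
        if len(years) < 4:
            raise ValidationError("need at least 4 years")
        if np.any(np.diff(years) != 1):
            raise ValidationError("years must be consecutive")
        if a.shape != (len(self.ages),) or b.shape != (len(self.ages),):
            raise ValidationError("a_x/b_x must have one value per age group")
        if abs(b.sum() - 1.0) > 1e-10:
            raise ValidationError("b_x must sum to 1 (within 1e-10)")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.kt_regime not in ("linear", "rw_drift", "piecewise_nonlinear"):
            raise ValidationError(f"unknown kt regime {self.kt_regime!r}")


@dataclass(frozen=True)
class SyntheticTruth:
    """A realized surface together with the ground truth that generated it."""

    spec: SyntheticSpec
    kt_true: np.ndarray
    surface: MortalitySurface

    @property
    def true_log_rates(self) -> np.ndarray:
        """Noise-free log rates a_x + b_x k_t."""
        return self.spec.a_x[:, None] + np.outer(self.spec.b_x, self.kt_true)


def _realize_kt(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    n = len(spec.years)
    p = spec.kt_params
    if spec.kt_regime == "linear":
        slope = float(p["slope"])
        kt = slope * np.arange(n, dtype=float)
    elif spec.kt_regime == "rw_drift":
        drift = float(p["drift"])
        sigma = float(p["sigma"])
        steps = drift + sigma * rng.standard_normal(n - 1)
        kt = np.concatenate([[0.0], np.cumsum(steps)])
    else:  # piecewise_nonlinear
        bps = [int(b) for b in p["breakpoints"]]
        slopes = [float(s) for s in p["slopes"]]
        if len(slopes) != len(bps) + 1:
            raise ValidationError("need one more slope than breakpoints")
        y0, y1 = int(spec.years[0]), int(spec.years[-1])
        if not all(y0 < b < y1 for b in bps) or bps != sorted(bps):
            raise ValidationError(
                f"breakpoints {bps} must be ordered and strictly inside "
                f"[{y0}, {y1}]"
            )
        seg = np.searchsorted(np.array(bps), spec.years[1:], side="left")
        increments = np.array(slopes)[seg]
        kt = np.concatenate([[0.0], np.cumsum(increments)])
    return kt - kt.mean()


def simulate_lc_surface(spec: SyntheticSpec) -> SyntheticTruth:
    """Draw one surface from the log-bilinear generative model.

    The realized period index is centered to sum to zero so (a_x, b_x, k_t)
    is identified exactly as an SVD-based fit would normalize it.
    """
    rng = np.random.default_rng(spec.seed)
    kt = _realize_kt(spec, rng)
    logm = spec.a_x[:, None] + np.outer(spec.b_x, kt)
    if spec.noise_sigma > 0:
        logm = logm + spec.noise_sigma * rng.standard_normal(logm.shape)
    surface = MortalitySurface(spec.ages, spec.years, np.exp(logm))
    return SyntheticTruth(spec=spec, kt_true=kt, surface=surface)


# -- two-subpopulation scenario ------------------------------------------

#: Annual proportional decline of child mortality (5.1%/year), the
#: long-run average pace observed in the child groups.
DEFAULT_CHILD_DECLINE = 0.051


#: Slower child decline pace after the training era (3.9%/year).
DEFAULT_CHILD_DECLINE_LATE = 0.039


def child_spec(years: Sequence[int], seed: int,
               annual_decline: float = DEFAULT_CHILD_DECLINE,
               noise_sigma: float = 0.05,
               slowdown_year: int | None = None,
               late_decline: float = DEFAULT_CHILD_DECLINE_LATE
               ) -> SyntheticSpec:
    """Child subpopulation (groups 0, 1-4, 5-9, 10-14): linear log decline.

    With uniform loadings, each group's rate falls by ``annual_decline``
    per year, i.e. the year-on-year rate ratio is 1 - annual_decline.
    If ``slowdown_year`` is given, the pace eases to ``late_decline`` per
    year from that year on — the documented slackening of child mortality
    improvement after the early-2010s.
    """
    grid = default_age_grid()
    child = grid.subset(grid.labels[:4])
    n = len(child)
    b = np.full(n, 1.0 / n)
    slope_k = np.log(1.0 - annual_decline) * n  # b_x * slope_k = log ratio
    if slowdown_year is None:
        regime = "linear"
        params: dict = {"slope": slope_k}
    else:
        regime = "piecewise_nonlinear"
        params = {"breakpoints": (int(slowdown_year),),
                  "slopes": (slope_k, np.log(1.0 - late_decline) * n)}
    return SyntheticSpec(
        ages=child, years=np.asarray(years, dtype=int),
        a_x=default_baseline_log_rates()[:4], b_x=b,
        kt_regime=regime, kt_params=params,
        noise_sigma=noise_sigma, seed=seed,
    )


def adult_spec(years: Sequence[int], seed: int,
               breakpoints: tuple[int, int] = (1998, 2007),
               log_slopes: tuple[float, float, float] = (0.05, -0.005, -0.03),
               noise_sigma: float = 0.02) -> SyntheticSpec:
    """Adult subpopulation (15-19 and older): rise, plateau, decline.

    ``log_slopes`` are per-year changes of each adult log rate in the three
    segments: the sharp post-independence mortality rise of the 1990s
    (~5%/year on the log scale), near-stagnation, then the sustained
    decline that set in during the late 2000s.
    """
    grid = default_age_grid()
    adult = grid.subset(grid.labels[4:])
    n = len(adult)
    b = np.full(n, 1.0 / n)
    slopes_k = tuple(s * n for s in log_slopes)
    return SyntheticSpec(
        ages=adult, years=np.asarray(years, dtype=int),
        a_x=default_baseline_log_rates()[4:], b_x=b,
        kt_regime="piecewise_nonlinear",
        kt_params={"breakpoints": breakpoints, "slopes": slopes_k},
        noise_sigma=noise_sigma, seed=seed,
    )


def simulate_two_subpop(spec_child: SyntheticSpec,
                        spec_adult: SyntheticSpec) -> MortalitySurface:
    """Stack a linear-trend child block on a nonlinear adult block."""
    if set(spec_child.ages.labels) & set(spec_adult.ages.labels):
        raise ValidationError("child and adult age labels overlap")
    if not np.array_equal(spec_child.years, spec_adult.years):
        raise ValidationError("child and adult year ranges must match")
    child = simulate_lc_surface(spec_child).surface
    adult = simulate_lc_surface(spec_adult).surface
    labels = spec_child.ages.labels + spec_adult.ages.labels
    mids = np.concatenate([spec_child.ages.midpoints, spec_adult.ages.midpoints])
    grid = AgeGrid(labels, mids)
    rates = np.vstack([child.rates, adult.rates])
    return MortalitySurface(grid, spec_child.years, rates)


def study_scenario(years: Sequence[int], seed: int,
                   slowdown_year: int | None = 2013
                   ) -> tuple[MortalitySurface, ExogenousTable]:
    """The full synthetic study condition: a 19-group surface whose child
    block declines linearly (5.1%/year, easing to 3.9%/year from
    ``slowdown_year``) while the adult block follows the nonlinear
    rise-plateau-decline period index, plus matching exogenous series."""
    years = np.asarray(years, dtype=int)
    c = child_spec(years, seed=seed, slowdown_year=slowdown_year)
    a = adult_spec(years, seed=seed + 1)
    surface = simulate_two_subpop(c, a)
    exog = simulate_exogenous(years, seed=seed + 2)
    return surface, exog


def simulate_exogenous(years: Sequence[int], seed: int) -> ExogenousTable:
    """Macro covariates with the qualitative shapes of the study period.

    GDP per capita grows steadily, then dips and recovers in the final
    third; population follows a U (decline then recovery); doctor density
    is near-constant with small fluctuations.
    """
    years = np.asarray(years, dtype=int)
    n = len(years)
    if n < 4:
        raise ValidationError("need at least 4 years")
    rng = np.random.default_rng(seed)
    t = np.arange(n, dtype=float)

    # GDP: log path with growth, a two-year dip at ~70% of the range, recovery
    t_dip = max(2, int(round(0.7 * (n - 1))))
    incr = np.full(n - 1, 0.09)
    if t_dip < n - 1:
        incr[t_dip - 1] = -0.08
    if t_dip < n - 2:
        incr[t_dip] = -0.05
    incr[t_dip + 1:] = 0.05
    log_gdp = np.log(1200.0) + np.concatenate([[0.0], np.cumsum(incr)])
    gdp = np.exp(log_gdp + 0.01 * rng.standard_normal(n))

    # Population: U-shape with minimum around 45% of the range
    t_min = 0.45 * (n - 1)
    popul = 16.5e6 - 1.8e6 * np.exp(-((t - t_min) / (0.45 * max(n - 1, 1))) ** 2)
    popul = popul * (1.0 + 0.002 * rng.standard_normal(n))

    # Doctor density per 1000: flat with small noise (CV well under 5%)
    doctors = 3.55 + 0.04 * rng.standard_normal(n)

    df = pd.DataFrame({"GDP": gdp, "Doctors": doctors, "Popul": popul},
                      index=years)
    return ExogenousTable(df)


def inject_outliers(surface: MortalitySurface, years: Iterable[int],
                    multiplier: float) -> MortalitySurface:
    """Multiply whole year columns by ``multiplier`` (pandemic-style shock)."""
    if multiplier <= 0:
        raise ValidationError("multiplier must be positive")
    ys = {int(y) for y in years}
    have = {int(y) for y in surface.years}
    missing = ys - have
    if missing:
        raise ValidationError(f"year {min(missing)} outside surface range")
    rates = surface.rates.copy()
    for j, y in enumerate(surface.years):
        if int(y) in ys:
            rates[:, j] *= multiplier
    return MortalitySurface(surface.ages, surface.years, rates)
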