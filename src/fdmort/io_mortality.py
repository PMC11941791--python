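"""Containers and I/O for age-specific mortality surfaces and exogenous factors.

The central object is :class:`MortalitySurface`, an age x year matrix of
death rates m_{x,t} (deaths per person-year).  Rates are always held
internally per person-year; the "per 1000" convention common in published
tables appears only at read/write time.

Age groups follow the standard abridged layout: 0, 1-4, 5-9, ..., 80-84,
85+.  Each group carries a representative midpoint age (in years) used when
evaluating spline/Fourier bases over age.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError

__all__ = [
    "AgeGrid",
    "MortalitySurface",
    "ExogenousTable",
    "default_age_grid",
    "read_rates",
    "write_rates",
    "read_exogenous",
    "write_exogenous",
    "replace_years_by_interpolation",
    "log_rates",
]

#: Standard 19-group abridged age grid.
DEFAULT_AGE_LABELS: tuple[str, ...] = ("0", "1-4") + tuple(
    f"{lo}-{lo + 4}" for lo in range(5, 85, 5)
) + ("85+",)

#: Representative ages: 0.5 for infants, interval midpoints for closed
#: groups, 90 for the open-ended 85+ group.
DEFAULT_AGE_MIDPOINTS: tuple[float, ...] = (0.5, 3.0) + tuple(
    lo + 2.5 for lo in range(5, 85, 5)
) + (90.0,)


@dataclass(frozen=True)
class AgeGrid:
    """Ordered age-group labels with representative midpoint ages (years)."""

    labels: tuple[str, ...]
    midpoints: np.ndarray

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        mids = np.asarray(self.midpoints, dtype=float)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "midpoints", mids)
        if len(labels) == 0:
            raise ValidationError("AgeGrid needs at least one age group")
        if len(set(labels)) != len(labels):
            raise ValidationError("age-group labels must be unique")
        if mids.ndim != 1 or len(mids) != len(labels):
            raise ValidationError("midpoints must align with labels")
        if not np.all(np.isfinite(mids)):
            raise ValidationError("midpoints must be finite")
        if np.any(np.diff(mids) <= 0):
            raise ValidationError("midpoints must be strictly increasing")

    def __len__(self) -> int:
        return len(self.labels)

    def index_of(self, labels: Iterable[str]) -> np.ndarray:
        pos = {lab: i for i, lab in enumerate(self.labels)}
        try:
            return np.array([pos[str(l)] for l in labels], dtype=int)
        except KeyError as exc:
            raise ValidationError(f"unknown age group {exc.args[0]!r}") from None

    def subset(self, labels: Iterable[str]) -> "AgeGrid":
        idx = self.index_of(labels)
        return AgeGrid(tuple(self.labels[i] for i in idx), self.midpoints[idx])


def default_age_grid() -> AgeGrid:
    """The 19-group grid 0, 1-4, 5-9, ..., 80-84, 85+."""
    return AgeGrid(DEFAULT_AGE_LABELS, np.array(DEFAULT_AGE_MIDPOINTS))


def _midpoint_from_label(label: str) -> float:
    label = label.strip().replace("–", "-")  # tolerate en-dash
    if re.fullmatch(r"\d+", label):
        return float(label) + 0.5
    m = re.fullmatch(r"(\d+)\s*-\s*(\d+)", label)
    if m:
        lo, hi = int(m.group(1)), int(m.group(2))
        return (lo + hi + 1) / 2.0
    m = re.fullmatch(r"(\d+)\s*\+", label)
    if m:
        return float(m.group(1)) + 5.0
    raise ValidationError(
        f"cannot infer a midpoint for age label {label!r}; pass an AgeGrid explicitly"
    )


@dataclass(frozen=True)
class MortalitySurface:
    """Age x year matrix of death rates (deaths per person-year)."""

    ages: AgeGrid
    years: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "rates", rates)
        if years.ndim != 1 or len(years) == 0:
            raise ValidationError("years must be a non-empty 1-d sequence")
        if len(years) > 1 and not np.all(np.diff(years) == 1):
            raise ValidationError("calendar years must be consecutive with no gaps")
        if rates.shape != (len(self.ages), len(years)):
            raise ValidationError(
                f"rates shape {rates.shape} does not match "
                f"{len(self.ages)} ages x {len(years)} years"
            )
        if not np.all(np.isfinite(rates)):
            raise ValidationError("all rates must be finite")
        if np.any(rates <= 0):
            bad = np.argwhere(rates <= 0)[0]
            raise ValidationError(
                f"non-positive rate at age {self.ages.labels[bad[0]]!r}, "
                f"year {years[bad[1]]}"
            )

    @property
    def n_ages(self) -> int:
        return len(self.ages)

    @property
    def n_years(self) -> int:
        return len(self.years)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rates, index=list(self.ages.labels),
                            columns=list(self.years))

    def subset_ages(self, labels: Sequence[str]) -> "MortalitySurface":
        idx = self.ages.index_of(labels)
        return MortalitySurface(self.ages.subset(labels), self.years,
                                self.rates[idx])

    def subset_years(self, years: Sequence[int]) -> "MortalitySurface":
        years = np.asarray(years, dtype=int)
        pos = {int(y): j for j, y in enumerate(self.years)}
        try:
            cols = [pos[int(y)] for y in years]
        except KeyError as exc:
            raise ValidationError(f"year {exc.args[0]} not in surface") from None
        return MortalitySurface(self.ages, years, self.rates[:, cols])


def log_rates(surface: MortalitySurface) -> np.ndarray:
    """Natural-log death rates, same shape as ``surface.rates``."""
    return np.log(surface.rates)


def read_rates(path: str | Path, unit: str = "per_person",
               age_grid: AgeGrid | None = None) -> MortalitySurface:
    """Read a rates CSV: first column age labels, header row calendar years.

    ``unit='per_1000'`` divides the body by 1000 so the returned surface is
    always per person-year.
    """
    if unit not in ("per_person", "per_1000"):
        raise ValidationError(f"unknown unit {unit!r}")
    df = pd.read_csv(path, index_col=0)
    try:
        years = np.array([int(c) for c in df.columns])
    except ValueError as exc:
        raise ParseError(f"non-integer year in header: {exc}") from None
    body = df.apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any():
        i, j = np.argwhere(body.isna().to_numpy())[0]
        raise ParseError(
            f"non-numeric cell at age row {df.index[i]!r}, year column {years[j]}"
        )
    order = np.argsort(years)
    years = years[order]
    rates = body.to_numpy(dtype=float)[:, order]
    if np.any(rates <= 0):
        i, j = np.argwhere(rates <= 0)[0]
        raise ValidationError(
            f"non-positive rate at age {df.index[i]!r}, year {years[j]}"
        )
    if len(years) > 1 and not np.all(np.diff(years) == 1):
        missing = int(years[np.argmax(np.diff(years) > 1)]) + 1
        raise ValidationError(f"years are not consecutive (missing {missing})")
    if unit == "per_1000":
        rates = rates / 1000.0
    labels = tuple(str(x) for x in df.index)
    if age_grid is None:
        mids = np.array([_midpoint_from_label(l) for l in labels])
        age_grid = AgeGrid(labels, mids)
    elif tuple(age_grid.labels) != labels:
        raise ValidationError("age_grid labels do not match file rows")
    return MortalitySurface(age_grid, years, rates)


def write_rates(surface: MortalitySurface, path: str | Path,
                unit: str = "per_person") -> None:
    if unit not in ("per_person", "per_1000"):
        raise ValidationError(f"unknown unit {unit!r}")
    scale = 1000.0 if unit == "per_1000" else 1.0
    df = surface.to_frame() * scale
    df.index.name = "age_group"
    df.to_csv(path, float_format="%.17g")


def replace_years_by_interpolation(
    surface: MortalitySurface, years_to_replace: Iterable[int]
) -> MortalitySurface:
    """Replace outlier years by linear interpolation on the log-rate scale.

    For each age group the log-rate at every replaced year is interpolated
    linearly between the nearest non-replaced flanking years.  Used to level
    out atypical mortality shocks (e.g. pandemic years) before fitting
    trend models.
    """
    repl = sorted({int(y) for y in years_to_replace})
    if not repl:
        return surface
    yrs = set(int(y) for y in surface.years)
    for y in repl:
        if y not in yrs:
            raise ValidationError(f"year {y} not in surface")
    kept = np.array([y for y in surface.years if int(y) not in set(repl)])
    if len(kept) == 0:
        raise ValidationError("cannot replace every year")
    for y in repl:
        if y < kept.min() or y > kept.max():
            raise ValidationError(
                f"year {y} has no non-replaced flanking year on both sides"
            )
    keep_cols = np.array([int(y) not in set(repl) for y in surface.years])
    logm = np.log(surface.rates)
    out = logm.copy()
    repl_years = np.array(repl, dtype=float)
    for i in range(surface.n_ages):
        out[i, ~keep_cols] = np.interp(repl_years, kept.astype(float),
                                       logm[i, keep_cols])
    return replace(surface, rates=np.exp(out))


@dataclass(frozen=True)
class ExogenousTable:
    """Yearly exogenous factor series (e.g. GDP per capita, doctor density,
    population size) used to regress principal-component scores on."""

    data: pd.DataFrame  # index: calendar years; columns: factor names

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = int(df.index[df.index.duplicated()][0])
            raise ValidationError(f"duplicated year {dup}")
        if df.columns.has_duplicates:
            raise ValidationError("duplicated factor name")
        if df.isna().any().any():
            i, j = np.argwhere(df.isna().to_numpy())[0]
            raise ValidationError(
                f"missing value for factor {df.columns[j]!r} in year {df.index[i]}"
            )
        df = df.sort_index()
        df.index = df.index.astype(int)
        object.__setattr__(self, "data", df.astype(float))

    @property
    def years(self) -> np.ndarray:
        return self.data.index.to_numpy()

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    def subset_years(self, years: Sequence[int]) -> "ExogenousTable":
        years = [int(y) for y in years]
        missing = [y for y in years if y not in self.data.index]
        if missing:
            raise ValidationError(f"exogenous table missing year {missing[0]}")
        return ExogenousTable(self.data.loc[years])


def read_exogenous(path: str | Path) -> ExogenousTable:
    """Read a `year,<factor>,<factor>,...` CSV into an :class:`ExogenousTable`."""
    df = pd.read_csv(path)
    year_col = next((c for c in df.columns if c.lower() == "year"), None)
    if year_col is None:
        raise ParseError("exogenous CSV must have a 'year' column")
    body = df.set_index(year_col)
    body = body.apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any():
        i, j = np.argwhere(body.isna().to_numpy())[0]
        raise ValidationError(
            f"missing or non-numeric value for factor {body.columns[j]!r} "
            f"in year {body.index[i]}"
        )
    return ExogenousTable(body)


def write_exogenous(table: ExogenousTable, path: str | Path) -> None:
    df = table.data.copy()
    df.index.name = "year"
    df.to_csv(path, float_format="%.17g")
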