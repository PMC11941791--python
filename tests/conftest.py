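import numpy as np
import pytest

from fdmort.io_mortality import AgeGrid, MortalitySurface, default_age_grid
from fdmort.synthetic_data import (
    SyntheticSpec,
    default_age_loadings,
    default_baseline_log_rates,
)

YEARS = np.arange(1991, 2024)          # 33 years
LAST_TRAIN_YEAR = 2013                 # 23 train + 10 test


@pytest.fixture(scope="session")
def years():
    return YEARS.copy()


@pytest.fixture(scope="session")
def grid():
    return default_age_grid()


@pytest.fixture
def rw_spec(grid):
    """19x33 random-walk-with-drift spec used by several recovery tests."""
    def make(seed, noise_sigma=0.02, drift=-0.5, sigma=0.2, n_years=33):
        yrs = YEARS[:n_years]
        return SyntheticSpec(
            ages=grid, years=yrs,
            a_x=default_baseline_log_rates(),
            b_x=default_age_loadings(),
            kt_regime="rw_drift",
            kt_params={"drift": drift, "sigma": sigma},
            noise_sigma=noise_sigma, seed=seed,
        )
    return make


def random_surface(seed, n_ages=6, n_years=10, first_year=2000):
    """Arbitrary positive surface (log-uniform rates), for oracle checks."""
    rng = np.random.default_rng(seed)
    rates = np.exp(rng.uniform(np.log(1e-4), np.log(0.3),
                               size=(n_ages, n_years)))
    ages = AgeGrid(tuple(f"g{i}" for i in range(n_ages)),
                   np.arange(n_ages, dtype=float) * 5 + 2)
    return MortalitySurface(ages, np.arange(first_year, first_year + n_years),
                            rates)
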