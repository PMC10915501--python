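"""Shared fixtures: small synthetic environments and a cached recovery fit.

Everything is generated at test time from the package's own synthetic-data
module; the expensive pieces (a 500-event selection-recovery fit) are
session-scoped so several tests can share one computation.
"""

import numpy as np
import pandas as pd
import pytest

from knotflight.rsf import GAMSpec, build_design, fit_gam
from knotflight.simulate import (
    SimScenario,
    TrueSelection,
    default_regions,
    gen_departure_times,
    gen_env,
)

RECOVERY_TRUTH = TrueSelection(
    beta_wind=0.3, beta_cloud=-0.2, sunset_peak=108.0, tide_peak=-238.0
)


@pytest.fixture(scope="session")
def regions():
    return default_regions()


@pytest.fixture(scope="session")
def env_short():
    """Twelve days of synthetic tide/cloud/weather, enough for one 96-h window."""
    return gen_env("2019-10-01", "2019-10-13", seed=11)


@pytest.fixture(scope="session")
def env_season():
    """A forty-day environment used by the selection-recovery simulations."""
    return gen_env("2019-09-15", "2019-10-25", seed=7)


@pytest.fixture(scope="session")
def recovery_events(env_season):
    """500 departure times drawn from the known selection function."""
    grid = env_season.grid_10min()
    grid = grid[grid >= grid[0] + pd.Timedelta(hours=100)]
    return gen_departure_times(env_season, RECOVERY_TRUTH, 500, candidate_grid=grid, seed=21)


@pytest.fixture(scope="session")
def recovery_fit(env_season, recovery_events):
    """The weighted GAM fitted to the 500-event recovery design."""
    rng = np.random.default_rng(22)
    design = build_design(recovery_events, env_season, n_avail=30, rng=rng)
    with pytest.warns(UserWarning):
        # the single-season design has a constant year covariate, which is dropped
        fit = fit_gam(design, GAMSpec())
    return design, fit
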