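"""Shared fixtures: small grids and session-cached reference simulations."""

import numpy as np
import pytest
from hypothesis import settings

from monomict import forcing, simulate
from monomict.physics import ColumnGrid

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def grid():
    return ColumnGrid()


@pytest.fixture(scope="session")
def small_grid():
    return ColumnGrid(n_layers=8, dz=1.0)


@pytest.fixture(scope="session")
def biwa_run_6y():
    """Six-year default-scenario run (five detectable winters), shared by
    the emergence, analysis and acceptance tests."""
    cfg = forcing.ScenarioConfig.biwa_like(n_years=6, seed=1,
                                           start_year=1989)
    return cfg, simulate.run(cfg)


@pytest.fixture(scope="session")
def mechanism_pair():
    """Control vs suppressed-mixing paired runs (same forcing)."""
    cfg = forcing.ScenarioConfig.biwa_like(n_years=2, seed=3)
    control = simulate.run(cfg)
    suppressed = simulate.run(cfg, suppress_mixing=True)
    return control, suppressed


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
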