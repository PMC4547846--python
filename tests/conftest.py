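"""Shared fixtures: canonical parameter sets and expensive steady states.

Session-scoped fixtures hold the two costly computations reused across
modules: the criterion-style source-strength sweep of the trans model and
the calibrated detailed-model steady state used for the effective-exponent
fit.
"""

import numpy as np
import pytest

from pom1grad.model_core import ModelParams
from pom1grad.pde_solver import (
    SolverSettings,
    SpatialGrid,
    calibrate_beta,
    fit_effective_gamma,
)
from pom1grad.pipeline import prediction_sweep


@pytest.fixture(scope="session")
def trans_params():
    """Canonical trans model: D=1, alpha=6, S=2 -> C=1, x0=1, A=1."""
    return ModelParams(D=1.0, alpha=6.0, source_strength=2.0)


@pytest.fixture(scope="session")
def half_cell_grid():
    """Half-cell domain at 0.01 um resolution."""
    return SpatialGrid(length=7.0, n_points=701)


@pytest.fixture(scope="session")
def coarse_grid():
    """Fast grid (dx = 0.05 um) for tests that only need qualitative shape."""
    return SpatialGrid(length=7.0, n_points=141)


@pytest.fixture(scope="session")
def trans_sweep(trans_params, half_cell_grid):
    """15-point geometric source sweep over two decades, numerical steady
    states with a narrow (0.05 um) source band, interior power-law
    extraction of amplitude/decay length/total."""
    return prediction_sweep(
        trans_params, half_cell_grid, SolverSettings(),
        n_points=15, decades=2.0, source_width=0.05,
    )


@pytest.fixture(scope="session")
def detailed_gamma_fit():
    """Calibrated detailed model (N=6, kappa_i = i*0.5/min, beta*A ~ 5*0.5)
    solved on a domain long enough for the exponent fit to be
    domain-converged, plus its fitted effective exponent."""
    grid = SpatialGrid(length=21.0, n_points=2101)
    settings = SolverSettings()
    base = ModelParams(
        model_kind="detailed", D=1.0, beta=1.0,
        kappa=[0.5 * i for i in range(7)],
        source_strength=2.0, source_width=0.3,
    )
    params, steady = calibrate_beta(
        base, grid, settings, target_ratio=5.0, kappa_unit=0.5
    )
    fit = fit_effective_gamma(params, grid, settings, steady=steady)
    return {"params": params, "steady": steady, "fit": fit, "grid": grid}
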