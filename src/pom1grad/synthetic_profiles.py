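"""Synthetic cortical-profile populations.

Generates paired Pom1/Tea4 intensity profiles for a population of cells with
the statistical structure of pole-quantified microscopy data: log-normal
pole-to-pole variation of the Tea4 source, systematic within-cell
differences between poles, multiplicative (shot/speckle) measurement noise,
and a constant additive background.  The Pom1 profile of each pole is the
deterministic steady state of a chosen gradient model driven by that pole's
source strength, so the population encodes exactly the buffering structure
the analysis stage is meant to recover: under the trans model the Pom1
amplitude scales as S^(2/3), which compresses Tea4 variability and makes
Pom1 pole levels less variable than Tea4 levels.

The generator emulates the *output* of cortical-profile quantification
(tidy per-position intensity tables), not micrographs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model_core import (
    GradientProfile,
    InvalidParameterError,
    ModelParams,
    analytic_steady_state,
    cis_steady_state,
)
from . import pde_solver

__all__ = [
    "PopulationSpec",
    "ProfileTable",
    "PopulationDiagnostics",
    "InsufficientDataError",
    "sample_population",
    "population_diagnostics",
]


class InsufficientDataError(ValueError):
    """Too few cells/poles for a population-level statistic."""


@dataclass
class PopulationSpec:
    """Parameters of one synthetic cell population.

    Defaults mirror the structure of the quantified imaging dataset:
    97 cells with 4 profiles each (two poles, two cortex sides) = 388
    profiles; Tea4 source strengths log-normal across poles
    (``tea4_log_sd`` is the SD of the natural log, 0.35 giving a roughly
    four-fold 95% spread); secondary profiles scaled by a uniform-in-log
    factor in [1/2, 1] so that within-cell amplitudes differ two- to
    four-fold; 10% multiplicative measurement noise per sampled position;
    sampling every 0.1 um out to 4 um from the pole tip.

    The default generative model is the trans gradient with D = 1 um^2/min
    and alpha = 0.45 at median source strength 2, placing the median decay
    length near 1 um — the scale of measured cortical kinase gradients and
    well resolved by the 0.1 um sampling and 0.3 um analysis windows.
    Scaling exponents do not depend on this scale choice.
    """

    n_cells: int = 97
    profiles_per_cell: int = 4
    tea4_log_sd: float = 0.35
    within_cell_factor_range: tuple[float, float] = (0.5, 1.0)
    noise_cv: float = 0.1
    background: float = 0.05
    pixel_size: float = 0.1
    max_arclength: float = 4.0
    generative_model: ModelParams = field(
        default_factory=lambda: ModelParams(alpha=0.45, source_strength=2.0)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise InvalidParameterError("n_cells must be >= 1")
        if self.profiles_per_cell < 1:
            raise InvalidParameterError("profiles_per_cell must be >= 1")
        if self.noise_cv < 0:
            raise InvalidParameterError("noise_cv must be >= 0")
        if self.pixel_size <= 0 or self.max_arclength <= self.pixel_size:
            raise InvalidParameterError("need 0 < pixel_size < max_arclength")
        lo, hi = self.within_cell_factor_range
        if not (0 < lo <= hi):
            raise InvalidParameterError("within_cell_factor_range must satisfy 0 < lo <= hi")
        if self.seed is None:
            raise InvalidParameterError("seed is mandatory for reproducibility")

    @property
    def positions(self) -> np.ndarray:
        n = int(round(self.max_arclength / self.pixel_size)) + 1
        return np.arange(n) * self.pixel_size

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "n_cells", "profiles_per_cell", "tea4_log_sd", "noise_cv",
            "background", "pixel_size", "max_arclength", "seed")}
        d["within_cell_factor_range"] = list(self.within_cell_factor_range)
        d["generative_model"] = self.generative_model.to_dict()
        return d


@dataclass
class ProfileTable:
    """Tidy per-position intensity table plus per-cell metadata.

    ``data`` columns: cell_id, pole_id, position_um, pom1, tea4.
    ``cell_metadata`` columns: cell_id, cytoplasmic_pom1, cell_length.
    Every pole shares the same position sampling.
    """

    data: pd.DataFrame
    cell_metadata: pd.DataFrame
    spec: Optional[PopulationSpec] = None

    def n_poles(self) -> int:
        return self.data.groupby(["cell_id", "pole_id"]).ngroups

    def positions(self) -> np.ndarray:
        first = self.data.groupby(["cell_id", "pole_id"]).ngroup() == 0
        return self.data.loc[first, "position_um"].to_numpy()

    def iter_poles(self):
        """Yield ((cell_id, pole_id), sub-frame) per pole, in table order."""
        return self.data.groupby(["cell_id", "pole_id"], sort=False)

    def to_csv(self, path) -> None:
        """Write the tidy CSV plus a sibling ``<stem>.meta.json``."""
        path = Path(path)
        self.data.to_csv(path, index=False)
        meta = {
            "cells": self.cell_metadata.to_dict(orient="records"),
            "spec": self.spec.to_dict() if self.spec is not None else None,
        }
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path) -> "ProfileTable":
        path = Path(path)
        data = pd.read_csv(path)
        meta_path = path.with_suffix(".meta.json")
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            cells = pd.DataFrame(meta["cells"])
        else:
            cells = pd.DataFrame({"cell_id": sorted(data["cell_id"].unique())})
        return cls(data=data, cell_metadata=cells)


def _noiseless_profile(params: ModelParams, positions: np.ndarray) -> np.ndarray:
    """Steady-state Pom1 profile for one pole's source strength."""
    kind = params.model_kind
    if kind == "trans":
        return analytic_steady_state(params, _Grid(positions)).values
    if kind == "cis":
        return cis_steady_state(params, _Grid(positions)).values
    # cluster/combined/detailed need the numerical solver on its own grid
    grid = pde_solver.SpatialGrid(length=max(7.0, positions[-1]), n_points=701)
    steady = pde_solver.solve_to_steady_state(params, grid)
    return np.interp(positions, grid.positions, steady.values)


class _Grid:
    """Minimal positions-only grid adapter for the analytic closed forms."""

    def __init__(self, positions: np.ndarray):
        self.positions = positions


def sample_population(spec: PopulationSpec) -> ProfileTable:
    """Draw one synthetic population; bit-identical for a given seed.

    Per pole: a Tea4 source strength S (log-normal around the generative
    model's ``source_strength``, multiplied by the within-cell factor for
    secondary profiles), a half-Gaussian Tea4 cap of integral proportional
    to S, and the noiseless Pom1 steady state for that S; both channels
    then get mean-one multiplicative log-normal noise (``noise_cv``) and
    the additive background.
    """
    rng = np.random.default_rng(spec.seed)
    x = spec.positions
    gm = spec.generative_model
    base_S = gm.source_strength
    sigma_noise = float(np.sqrt(np.log1p(spec.noise_cv**2)))
    lo, hi = spec.within_cell_factor_range

    rows = []
    meta = []
    for c in range(spec.n_cells):
        cell_S = base_S * np.exp(rng.normal(0.0, spec.tea4_log_sd))
        meta.append({
            "cell_id": c,
            # cytoplasmic pool varies a bit over twofold across the
            # population, uncorrelated with the pole source
            "cytoplasmic_pom1": float(np.exp(rng.normal(0.0, 0.18))),
            "cell_length": float(rng.normal(10.0, 1.0)),
        })
        for j in range(spec.profiles_per_cell):
            if j == 0:
                factor = 1.0
            else:
                factor = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            S = cell_S * factor
            try:
                pom1 = _noiseless_profile(replace(gm, source_strength=S), x)
            except (pde_solver.ConvergenceError, pde_solver.StabilityError) as err:
                raise type(err)(
                    f"generative model failed for cell {c} pole {j}: {err}",
                    *([] if not hasattr(err, "residual") else [err.residual]),
                ) from err
            tea4 = S * np.exp(-0.5 * (x / gm.source_width) ** 2)
            if spec.noise_cv > 0:
                mu = -0.5 * sigma_noise**2
                pom1 = pom1 * rng.lognormal(mu, sigma_noise, size=x.size)
                tea4 = tea4 * rng.lognormal(mu, sigma_noise, size=x.size)
            pom1 = pom1 + spec.background
            tea4 = tea4 + spec.background
            rows.append(pd.DataFrame({
                "cell_id": c,
                "pole_id": j,
                "position_um": x,
                "pom1": pom1,
                "tea4": tea4,
            }))
    return ProfileTable(
        data=pd.concat(rows, ignore_index=True),
        cell_metadata=pd.DataFrame(meta),
        spec=spec,
    )


@dataclass
class PopulationDiagnostics:
    """Population-level variability summaries of a profile table."""

    pom1_amplitude_cv: float
    tea4_amplitude_cv: float
    within_cell_fold_min: float
    within_cell_fold_max: float
    bartlett_statistic: float
    bartlett_p_value: float
    n_poles: int


def population_diagnostics(table: ProfileTable) -> PopulationDiagnostics:
    """Pole-amplitude CVs, within-cell fold-ranges and the Bartlett test.

    Amplitudes are background-subtracted means over the first 0.3 um.  The
    Bartlett test compares the variances of log Pom1 and log Tea4 pole
    amplitudes: log-scale variance is a relative-variability measure, so a
    significant result with larger Tea4 variance shows that the source is
    noisier than the gradient it drives (the signature of buffering).
    """
    from .profile_analysis import bartlett_compare  # local: keeps import one-way

    if table.cell_metadata["cell_id"].nunique() < 2:
        raise InsufficientDataError("need at least 2 cells for diagnostics")
    amps_p, amps_t, folds = [], [], []
    for (cell, pole), sub in table.iter_poles():
        x = sub["position_um"].to_numpy()
        band = x <= x[0] + 0.3
        bg_p = sub["pom1"].min()
        bg_t = sub["tea4"].min()
        amps_p.append(max(sub["pom1"].to_numpy()[band].mean() - bg_p, 1e-12))
        amps_t.append(max(sub["tea4"].to_numpy()[band].mean() - bg_t, 1e-12))
    amps_p = np.asarray(amps_p)
    amps_t = np.asarray(amps_t)
    if amps_p.size < 2:
        raise InsufficientDataError("need at least 2 poles")

    df = pd.DataFrame({
        "cell": [k[0] for k, _ in table.iter_poles()],
        "amp": amps_p,
    })
    fold = df.groupby("cell")["amp"].agg(lambda a: a.max() / a.min())

    try:
        stat, p = bartlett_compare(np.log(amps_p), np.log(amps_t))
    except (ValueError, InvalidParameterError):
        # identical/degenerate samples: no variance to compare
        stat, p = float("nan"), float("nan")
    return PopulationDiagnostics(
        pom1_amplitude_cv=float(np.std(amps_p, ddof=1) / np.mean(amps_p)),
        tea4_amplitude_cv=float(np.std(amps_t, ddof=1) / np.mean(amps_t)),
        within_cell_fold_min=float(fold.min()),
        within_cell_fold_max=float(fold.max()),
        bartlett_statistic=stat,
        bartlett_p_value=p,
        n_poles=int(amps_p.size),
    )
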