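"""Simulated single-cell populations and destructive subsampling.

The generative model is a single protein whose abundance changes linearly
over an abstract unit time course::

    abundance = slope * time + intercept + eps,   eps ~ N(0, noise_sd**2)

with each cell's time drawn independently and uniformly from the time
range (default [0, 1]).  A *population* is a large cloud of such cells; a
*sample* is a small draw without replacement, standing in for one
destructive single-cell time-course experiment (a measured cell is lysed
and can never be measured again).

All randomness flows through :class:`numpy.random.Generator` seeded
explicitly, so every population and sample is exactly reproducible from
its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TextIO, Union

import numpy as np
import pandas as pd

from .exceptions import ParameterError

__all__ = [
    "PopulationSpec",
    "Population",
    "Sample",
    "simulate_population",
    "subsample",
    "cells_to_csv",
    "cells_from_csv",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Generative parameters for a simulated population.

    Parameters
    ----------
    slope
        Abundance change per unit pseudotime; 0 models a non-changing
        protein.
    intercept
        Baseline abundance at time 0 (default 1).
    noise_sd
        Standard deviation of the zero-mean Gaussian noise term; lumps
        together biological cell-to-cell heterogeneity and technical
        measurement error.
    n_cells
        Number of cells in the population (default 10,000).
    time_range
        Closed interval cells' times are drawn from (default (0, 1)).
    """

    slope: float = 1.0
    intercept: float = 1.0
    noise_sd: float = 0.25
    n_cells: int = 10_000
    time_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if int(self.n_cells) != self.n_cells or self.n_cells < 1:
            raise ParameterError(f"n_cells must be a positive integer, got {self.n_cells}")
        lo, hi = self.time_range
        if not lo < hi:
            raise ParameterError(f"time_range lower bound must be < upper, got {self.time_range}")


@dataclass(frozen=True, eq=False)
class Population:
    """A realized population: paired (time, abundance) values plus provenance."""

    times: np.ndarray
    abundances: np.ndarray
    spec: PopulationSpec
    seed: int

    def __post_init__(self) -> None:
        if len(self.times) != len(self.abundances):
            raise ParameterError("times and abundances must have equal length")
        if len(self.times) != self.spec.n_cells:
            raise ParameterError("population size does not match spec.n_cells")

    @property
    def n_cells(self) -> int:
        return self.spec.n_cells


@dataclass(frozen=True, eq=False)
class Sample:
    """A without-replacement draw of cells from a population."""

    times: np.ndarray
    abundances: np.ndarray
    n: int
    source_seed: int

    def __post_init__(self) -> None:
        if len(self.times) != self.n or len(self.abundances) != self.n:
            raise ParameterError("sample arrays must have length n")


def simulate_population(spec: PopulationSpec, seed: int) -> Population:
    """Simulate a population of single cells under the linear model.

    Times are i.i.d. uniform on ``spec.time_range``; abundances follow
    ``slope * time + intercept`` plus Gaussian noise of sd ``noise_sd``.
    The same ``(spec, seed)`` always yields bit-identical output.
    """
    rng = np.random.default_rng(seed)
    lo, hi = spec.time_range
    times = rng.uniform(lo, hi, size=spec.n_cells)
    noise = rng.normal(0.0, spec.noise_sd, size=spec.n_cells) if spec.noise_sd > 0 else 0.0
    abundances = spec.slope * times + spec.intercept + noise
    times.setflags(write=False)
    abundances = np.asarray(abundances)
    abundances.setflags(write=False)
    return Population(times=times, abundances=abundances, spec=spec, seed=seed)


def subsample(pop: Population, n: int, seed: int) -> Sample:
    """Draw ``n`` distinct cells uniformly without replacement.

    Models destructive measurement: one subsampling event corresponds to
    one full time-course experiment in which each measured cell is
    consumed.
    """
    if int(n) != n or n < 1:
        raise ParameterError(f"n must be a positive integer, got {n}")
    if n > pop.n_cells:
        raise ParameterError(f"n ({n}) exceeds the population size ({pop.n_cells})")
    rng = np.random.default_rng(seed)
    idx = rng.choice(pop.n_cells, size=n, replace=False)
    return Sample(
        times=pop.times[idx],
        abundances=pop.abundances[idx],
        n=int(n),
        source_seed=seed,
    )


PathOrBuf = Union[str, Path, TextIO]


def cells_to_csv(cells: Union[Population, Sample], path_or_buf: PathOrBuf) -> None:
    """Write cells as CSV with columns ``cell_id,time,abundance``.

    Floats are stored with 17 significant digits so the round trip
    through :func:`cells_from_csv` is bit-exact for double precision.
    """
    df = pd.DataFrame(
        {
            "cell_id": np.arange(len(cells.times)),
            "time": cells.times,
            "abundance": cells.abundances,
        }
    )
    df.to_csv(path_or_buf, index=False, float_format="%.17g")


def cells_from_csv(path_or_buf: PathOrBuf) -> pd.DataFrame:
    """Read a ``cell_id,time,abundance`` CSV written by :func:`cells_to_csv`."""
    df = pd.read_csv(path_or_buf, float_precision="round_trip")
    required = {"cell_id", "time", "abundance"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"cell CSV missing required columns: {sorted(missing)}")
    return df
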