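import numpy as np
import pytest

from sctempo.simulate import PopulationSpec, Sample, simulate_population
from sctempo.trajectory import GridSpec


@pytest.fixture
def default_grid():
    return GridSpec()


@pytest.fixture
def small_pop():
    """A small noisy population for fast subsampling tests."""
    return simulate_population(PopulationSpec(slope=1.0, noise_sd=0.5, n_cells=500), seed=42)


def make_sample(times, abundances, seed=0):
    times = np.asarray(times, dtype=float)
    abundances = np.asarray(abundances, dtype=float)
    return Sample(times=times, abundances=abundances, n=len(times), source_seed=seed)


@pytest.fixture
def sample_factory():
    return make_sample
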