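"""Estimating the slope/variation (S/V) ratio from data.

Real experiments do not know a protein's true slope or noise level. Both
are estimated from a subsample by ordinary least squares: the fitted
slope estimates S, the standard deviation of the residuals estimates V,
and their quotient is the S/V estimate. These tools characterize how
precise that estimate is at a given sample size and what a cutoff on the
estimated ratio retains of proteins at each true S/V.

The ratio uses |slope_est| — the ratio is an effect-size magnitude, and
under a truly flat protein noise produces negative fitted slopes as often
as positive ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats

from .exceptions import EstimationError, ParameterError
from .simulate import PopulationSpec, Sample, simulate_population
from .power import _batch_subsample_indices, _repeat_seeds

__all__ = [
    "SVEstimate",
    "SVErrorSummary",
    "RetentionResult",
    "estimate_sv",
    "sv_error_distribution",
    "filter_retention",
]

ResidDdof = Literal["sample", "regression"]


@dataclass(frozen=True)
class SVEstimate:
    """OLS-based slope, residual-spread and S/V-ratio estimates.

    ``ratio_est`` is ``inf`` when the residual spread is exactly zero
    (a noise-free sample); that is a flag, not an error.
    """

    slope_est: float
    variation_est: float
    ratio_est: float
    n: int


@dataclass(frozen=True, eq=False)
class SVErrorSummary:
    """Distribution of the estimation error (true S/V minus estimate)."""

    true_sv: float
    n_sample: int
    n_events: int
    mean_error: float
    sd_error: float
    quantiles: dict[float, float]
    errors: np.ndarray


@dataclass(frozen=True)
class RetentionResult:
    """Fraction of subsampling events surviving an estimated-S/V cutoff."""

    true_sv: float
    cutoff: float
    fraction_retained: float
    n_sample: int
    n_events: int


def _resid_ddof(n: int, mode: ResidDdof) -> int:
    # "sample": sd of the residuals as a plain sample sd (n-1);
    # "regression": the usual residual standard error (n-2).
    return n - 1 if mode == "sample" else n - 2


def estimate_sv(sample: Sample, resid_ddof: ResidDdof = "sample") -> SVEstimate:
    """Estimate S/V from one sample by ordinary least squares.

    The fitted slope of abundance on time estimates the slope; the
    standard deviation of the residuals estimates the variation; the
    reported ratio is |slope_est| / variation_est.  Exactly scale-free:
    multiplying all abundances by k > 0 scales both estimates by k and
    leaves the ratio unchanged.
    """
    if sample.n < 3:
        raise EstimationError(f"need at least 3 cells to estimate S/V, got {sample.n}")
    if np.unique(sample.times).size < 2:
        raise EstimationError("degenerate sample: all cells share one time value")
    fit = stats.linregress(sample.times, sample.abundances)
    resid = sample.abundances - (fit.intercept + fit.slope * sample.times)
    variation = float(np.sqrt(np.sum(resid**2) / _resid_ddof(sample.n, resid_ddof)))
    ratio = float(np.inf) if variation == 0 else abs(fit.slope) / variation
    return SVEstimate(slope_est=float(fit.slope), variation_est=variation,
                      ratio_est=float(ratio), n=sample.n)


def _batch_sv_estimates(
    times: np.ndarray, abund: np.ndarray, resid_ddof: ResidDdof
) -> np.ndarray:
    """Vectorized |slope|/resid-sd over rows of (batch, n) arrays."""
    n = times.shape[1]
    tc = times - times.mean(axis=1, keepdims=True)
    ac = abund - abund.mean(axis=1, keepdims=True)
    sxx = (tc**2).sum(axis=1)
    slope = (tc * ac).sum(axis=1) / sxx
    resid = ac - slope[:, None] * tc
    var = np.sqrt((resid**2).sum(axis=1) / _resid_ddof(n, resid_ddof))
    with np.errstate(divide="ignore"):
        return np.where(var > 0, np.abs(slope) / var, np.inf)


def _sv_event_ratios(
    slope: float,
    variation: float,
    n_sample: int,
    n_events: int,
    seed: int,
    population_size: int,
    resid_ddof: ResidDdof,
) -> np.ndarray:
    """S/V estimates from ``n_events`` subsamples of one simulated population."""
    if n_sample < 3:
        raise ParameterError(f"n_sample must be >= 3, got {n_sample}")
    (pop_seed, sub_seed), = _repeat_seeds(seed, 1)
    pop = simulate_population(
        PopulationSpec(slope=slope, noise_sd=variation, n_cells=population_size), pop_seed
    )
    rng = np.random.default_rng(sub_seed)
    idx = _batch_subsample_indices(rng, population_size, n_sample, n_events)
    return _batch_sv_estimates(pop.times[idx], pop.abundances[idx], resid_ddof)


def sv_error_distribution(
    true_sv: float,
    n_sample: int,
    n_events: int = 1000,
    seed: int = 0,
    slope: Optional[float] = None,
    variation: Optional[float] = None,
    population_size: int = 10_000,
    resid_ddof: ResidDdof = "sample",
    quantile_levels: Sequence[float] = (0.025, 0.25, 0.5, 0.75, 0.975),
) -> SVErrorSummary:
    """Distribution of (true S/V − estimated S/V) over repeated subsampling.

    The true ratio is realized by a concrete (slope, variation) pair; by
    default slope = ``true_sv`` and variation = 1, which is immaterial
    because the estimator is scale-free.  One large population is
    simulated and ``n_events`` subsamples of ``n_sample`` cells are drawn
    from it.
    """
    if slope is None and variation is None:
        slope, variation = true_sv, 1.0
    elif slope is None or variation is None:
        raise ParameterError("provide both slope and variation, or neither")
    if variation <= 0:
        raise ParameterError(f"variation must be > 0, got {variation}")
    if not np.isclose(abs(slope) / variation, true_sv):
        raise ParameterError(
            f"(slope={slope}, variation={variation}) does not realize true_sv={true_sv}"
        )
    ratios = _sv_event_ratios(slope, variation, n_sample, n_events, seed,
                              population_size, resid_ddof)
    errors = true_sv - ratios
    qs = {float(q): float(np.quantile(errors, q)) for q in quantile_levels}
    return SVErrorSummary(
        true_sv=true_sv,
        n_sample=n_sample,
        n_events=n_events,
        mean_error=float(errors.mean()),
        sd_error=float(errors.std(ddof=1)),
        quantiles=qs,
        errors=errors,
    )


def filter_retention(
    true_svs: Sequence[float],
    cutoff: float = 1.0,
    n_sample: int = 30,
    n_events: int = 1000,
    seed: int = 0,
    population_size: int = 1000,
    resid_ddof: ResidDdof = "sample",
) -> list[RetentionResult]:
    """Simulate cutoff-based filtering on the estimated S/V.

    For each true S/V, a population is simulated (slope = true_sv,
    variation = 1), ``n_events`` subsamples are drawn, and the fraction
    of events with estimated S/V >= ``cutoff`` is reported — the share of
    proteins at that quality level an experiment would retain.
    """
    true_svs = list(true_svs)
    if not true_svs:
        raise ParameterError("true_svs must be a non-empty list")
    if n_sample < 3:
        raise ParameterError(f"n_sample must be >= 3, got {n_sample}")
    child_seeds = [
        int(c.generate_state(1, dtype=np.uint32)[0]) & 0x7FFFFFFF
        for c in np.random.SeedSequence(seed).spawn(len(true_svs))
    ]
    results = []
    for sv, s in zip(true_svs, child_seeds):
        if sv < 0:
            raise ParameterError(f"true S/V must be >= 0, got {sv}")
        ratios = _sv_event_ratios(sv, 1.0, n_sample, n_events, s, population_size, resid_ddof)
        results.append(
            RetentionResult(
                true_sv=float(sv),
                cutoff=float(cutoff),
                fraction_retained=float(np.mean(ratios >= cutoff)),
                n_sample=n_sample,
                n_events=n_events,
            )
        )
    return results
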