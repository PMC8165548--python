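"""Monte-Carlo TP/FP engine and the ABC decision rule."""

import numpy as np
import pytest

from sctempo.exceptions import ParameterError, RateLookupError
from sctempo.power import (
    PowerTable,
    SVRatio,
    _batch_subsample_indices,
    _changing_fraction,
    classify_subsample,
    estimate_accuracy,
    estimate_fp_rate,
    sv_sweep,
)
from sctempo.simulate import PopulationSpec, simulate_population
from sctempo.trajectory import GridSpec, reference_line

FAST = dict(n_subsamples=300, n_repeats=3)
SMALL_POP = 2000


class TestClassifySubsample:
    def test_noise_free_sloped_sample_is_called_changing(self, sample_factory, default_grid):
        t = np.linspace(0, 1, 16)
        s = sample_factory(t, 1.0 * t + 1.0)
        truth = reference_line(1.0, 1.0, default_grid)
        alt = reference_line(0.0, s.abundances.mean(), default_grid)
        res = classify_subsample(s, truth, alt, "tp_run")
        assert res.abc_true < res.abc_alternative
        assert res.verdict == "changing"

    def test_exact_tie_is_conservatively_nonchanging(self, sample_factory, default_grid):
        # flat noise-free sample: the flat alternative fits exactly (ABC 0),
        # and a tie with an exactly-matching truth still goes to the null
        s = sample_factory(np.linspace(0, 1, 10), np.full(10, 2.0))
        flat = reference_line(0.0, 2.0, default_grid)
        res = classify_subsample(s, flat, flat, "tp_run")
        assert res.abc_true == res.abc_alternative == 0.0
        assert res.verdict == "nonchanging"

    def test_decision_rule_direction(self, sample_factory, default_grid):
        # interpolation is flat at c; truth 0.2 away, alternative 0.1 away
        s = sample_factory([0.2, 0.5, 0.8], [1.0, 1.0, 1.0])
        truth = reference_line(0.0, 1.2, default_grid)
        alt = reference_line(0.0, 1.1, default_grid)
        tp = classify_subsample(s, truth, alt, "tp_run")
        assert (tp.abc_true, tp.abc_alternative) == (pytest.approx(0.2), pytest.approx(0.1))
        assert tp.verdict == "nonchanging"
        # in an FP run the same geometry means the sloped alternative wins
        fp = classify_subsample(s, truth, alt, "fp_run")
        assert fp.verdict == "changing"

    def test_grid_mismatch_rejected(self, sample_factory, default_grid):
        s = sample_factory([0.5], [1.0])
        other = reference_line(0.0, 1.0, GridSpec(n_points=50))
        good = reference_line(0.0, 1.0, default_grid)
        with pytest.raises(ParameterError):
            classify_subsample(s, other, good, "tp_run")


class TestChangingFractionOracle:
    """The vectorized engine against an independent per-event recompute."""

    def test_tp_fraction_matches_manual_recompute(self, default_grid):
        pop = simulate_population(PopulationSpec(slope=1.0, noise_sd=0.5, n_cells=500), seed=21)
        rng = np.random.default_rng(77)
        idx = _batch_subsample_indices(rng, 500, 12, 40)
        # manual: classify each event through the public single-sample path
        from sctempo.simulate import Sample

        truth = reference_line(1.0, 1.0, default_grid)
        level = 1.0 * 0.5 + 1.0
        alt = reference_line(0.0, level, default_grid)
        manual = 0
        for row in idx:
            s = Sample(times=pop.times[row], abundances=pop.abundances[row], n=12, source_seed=0)
            manual += classify_subsample(s, truth, alt, "tp_run", default_grid).verdict == "changing"
        engine = _changing_fraction(pop, 12, default_grid, "tp_run", 40, sub_seed=77)
        assert engine == pytest.approx(manual / 40)


class TestEstimateAccuracy:
    def test_noise_free_accuracy_is_one_at_16_cells(self):
        est = estimate_accuracy(
            PopulationSpec(slope=1.0, noise_sd=0.0, n_cells=SMALL_POP), 16, seed=1, **FAST
        )
        assert est.rate == 1.0
        assert est.spread == 0.0

    def test_zero_slope_is_redirected_to_fp(self):
        with pytest.raises(ParameterError, match="estimate_fp_rate"):
            estimate_accuracy(PopulationSpec(slope=0.0), 16)

    def test_deterministic_under_seed(self):
        spec = PopulationSpec(slope=1.0, noise_sd=1.0, n_cells=SMALL_POP)
        a = estimate_accuracy(spec, 10, seed=5, **FAST)
        b = estimate_accuracy(spec, 10, seed=5, **FAST)
        assert a.rate == b.rate and a.repeat_rates == b.repeat_rates

    def test_monotone_in_n_and_noise_within_spread(self):
        spec = PopulationSpec(slope=1.0, noise_sd=1.0, n_cells=SMALL_POP)
        lo = estimate_accuracy(spec, 7, seed=2, **FAST)
        hi = estimate_accuracy(spec, 30, seed=3, **FAST)
        assert hi.rate >= lo.rate - 2 * max(lo.spread, hi.spread)
        quiet = estimate_accuracy(
            PopulationSpec(slope=1.0, noise_sd=0.25, n_cells=SMALL_POP), 16, seed=4, **FAST
        )
        noisy = estimate_accuracy(spec, 16, seed=5, **FAST)
        assert quiet.rate >= noisy.rate - 2 * max(quiet.spread, noisy.spread)


class TestEstimateFpRate:
    def test_noise_free_population_yields_no_false_positives(self):
        est = estimate_fp_rate(0.0, 1.0, 16, seed=1, population_size=SMALL_POP, **FAST)
        assert est.rate == 0.0

    def test_fp_rate_decreases_with_n(self):
        lo = estimate_fp_rate(1.0, 2.0, 7, seed=2, population_size=SMALL_POP, **FAST)
        hi = estimate_fp_rate(1.0, 2.0, 30, seed=3, population_size=SMALL_POP, **FAST)
        assert hi.rate <= lo.rate + 2 * max(lo.spread, hi.spread)

    def test_seven_cell_low_sv_fp_regime(self):
        # the small-sample danger zone: S/V <= 1 at n=7 has a high FP rate
        est = estimate_fp_rate(1.0, 1.0, 7, seed=4, population_size=SMALL_POP,
                               n_subsamples=500, n_repeats=3)
        assert est.rate >= 0.30

    def test_invalid_comparator_rejected(self):
        with pytest.raises(ParameterError, match="comparator_slope"):
            estimate_fp_rate(0.5, 0.0, 16)


class TestScaleInvariance:
    def test_rates_depend_only_on_the_sv_ratio(self):
        # (k*slope, k*variation) for k in {0.5, 2, 4} vs the base pair
        base = estimate_accuracy(
            PopulationSpec(slope=1.0, noise_sd=0.5, n_cells=SMALL_POP), 16, seed=6, **FAST
        )
        for k in (0.5, 2.0, 4.0):
            scaled = estimate_accuracy(
                PopulationSpec(slope=k * 1.0, noise_sd=k * 0.5, n_cells=SMALL_POP),
                16, seed=int(10 * k), **FAST,
            )
            spread = np.hypot(base.spread, scaled.spread)
            assert abs(scaled.rate - base.rate) <= 3 * max(spread, 0.02)


class TestSvSweepAndTable:
    def test_sweep_produces_tidy_rows_and_pooling(self):
        table = sv_sweep(
            [SVRatio(1.0, 0.5), SVRatio(2.0, 1.0)], [7, 16],
            n_subsamples=150, n_repeats=2, seed=8, population_size=SMALL_POP,
        )
        assert len(table.df) == 2 * 2 * 2  # realizations x n x kinds
        assert table.df["rate"].between(0, 1).all()
        pooled = table.pooled_rate(2.0, 16, "accuracy")
        rows = table.realizations(2.0, 16, "accuracy")
        assert pooled == pytest.approx(rows["rate"].mean())
        with pytest.raises(RateLookupError, match="n_sample=99"):
            table.pooled_rate(2.0, 99, "accuracy")

    def test_empty_realization_list_rejected(self):
        with pytest.raises(ParameterError):
            sv_sweep([], [16])

    def test_table_round_trips_through_csv(self, tmp_path):
        table = sv_sweep([SVRatio(2.0, 1.0)], [7], n_subsamples=50, n_repeats=2,
                         seed=9, population_size=500)
        path = tmp_path / "rates.csv"
        table.to_csv(path)
        back = PowerTable.from_csv(path)
        assert back.pooled_rate(2.0, 7, "fp_rate") == pytest.approx(
            table.pooled_rate(2.0, 7, "fp_rate")
        )

    def test_svratio_validation(self):
        with pytest.raises(ParameterError):
            SVRatio(0.0, 1.0)
        with pytest.raises(ParameterError):
            SVRatio(1.0, 0.0)
        assert SVRatio(3.0, 1.5).ratio == pytest.approx(2.0)
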