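# Methods

## Generative model

A simulated population is a cloud of `n_cells` independent cells, each a
single `(time, abundance)` pair:

- `time ~ Uniform(time_range)`, default `[0, 1]`. Pseudotime is
  abstract: 0 is the start of the transition, 1 the end. Uniform
  sampling models experiments that cannot control collection times
  (e.g. cells drawn from an asynchronously progressing tissue).
- `abundance = slope · time + intercept + ε`, `ε ~ N(0, noise_sd²)`.
  The noise term lumps biological cell-to-cell heterogeneity and
  technical measurement error; the model makes no attempt to separate
  them, because the detection problem depends only on their sum.

Defaults: `intercept = 1`, `n_cells = 10,000`. A *subsampling event*
draws `n` cells without replacement — measurement is destructive, so a
cell can appear at most once per experiment — and stands for one
complete time-course experiment with a budget of `n` cells.

All randomness flows through `numpy.random.Generator`. A run's seed is
split with `SeedSequence.spawn` into one child per repeat (and per sweep
cell), from which a population seed and a subsampling seed are derived;
every run is exactly reproducible and repeats are independent.

## Trajectory interpolation

A subsample is smoothed onto an equally spaced pseudotime grid by
Gaussian-kernel weighted averaging (Nadaraya–Watson regression):

```
value(t_k) = Σᵢ aᵢ wᵢₖ / Σᵢ wᵢₖ,   wᵢₖ = exp(−(tᵢ − t_k)² / (2 σ²))
```

with grid size 200 and bandwidth σ = 0.1 by default (the documented
defaults of the cellAlign interpolation whose concept this
re-implements; equivalence with that package's exact output is not
claimed). Weights are renormalized per grid point after subtracting the
smallest squared distance, so the output is always a convex combination
of the sample's abundances — bounded by their min and max and finite
even when raw weights underflow at tiny bandwidths.

The operator is exact on constant data and exactly equivariant under
shifting and scaling of the abundances. Because the reference curves
shift and scale the same way, the classification below is scale-free —
the property that lets all results collapse onto the S/V ratio.

No boundary correction is applied; the kernel's edge attenuation
affects every Monte-Carlo arm identically and therefore cancels from
the comparisons.

## The ABC decision rule

The distance between two curves sharing a grid is the mean absolute
difference over grid points — the area between curves (ABC) divided by
the range length, so values are comparable across grid resolutions.
Normalization is monotone and common to both arms of every comparison,
so it never changes a verdict.

- **TP runs** (truly changing protein): the interpolated trajectory is
  compared with the generative line (`ABC_true`) and with a flat null
  line (`ABC_null`); the event is called *changing* iff
  `ABC_true < ABC_null`.
- **FP runs** (truly flat protein): the population has slope 0; the
  trajectory is compared with the flat truth at the baseline level and
  with a sloped comparator of the stated slope (`ABC_falsepositive`);
  the event is a false positive iff the comparator is strictly closer.

Exact ties go to the null (non-changing) — conservative, and relevant
only to measure-zero events and the degenerate noise-free flat case.

### Anchoring the reference lines

The flat null and the sloped FP comparator need a vertical position.
Two conventions are implemented:

- `anchor="population"` (default): references sit at the population's
  true mean abundance (`slope · midpoint + intercept`; the simulator is
  an oracle and knows it). The FP comparator passes through the range
  midpoint at that level (`center_at_mean`), so the comparison is about
  shape, not offset.
- `anchor="subsample"`: references sit at each subsample's own mean.

The population anchor is the default because it reproduces the
published operating characteristics of this design problem
(16-cell accuracy ≈ 95% at noise 0.25 and ≈ 68% at noise 1.0; S/V = 2
rates of ≈ 80/15% at n = 16 and ≈ 90/5% at n = 30). Anchoring at the
subsample mean instead couples the null to the same data the trajectory
was built from; the null then fits noisy trajectories substantially
better and accuracy at high noise drops by >10 points. When classifying
*real* data with `classify_subsample`, no oracle exists — the caller
must supply both reference curves explicitly, and the subsample mean is
the natural, more conservative choice.

## Monte-Carlo protocol

One rate cell = 10 repeats × 1000 subsamples, each repeat re-simulating
the population with a fresh derived seed (so population-level sampling
noise is inside the error bars). The reported rate is the mean fraction
of events classified changing; `spread` is the sd across repeats. The
engine is vectorized over subsamples (batched kernel matrices and
batched OLS) and agrees event-for-event with the single-sample
`classify_subsample` path; a full cell runs in ~1–3 s on one CPU.

The S/V sweep realizes each ratio with several `(slope, variation)`
pairs (e.g. S/V = 2 as 1/0.5 and 2/1) and records per-realization rates,
so the scale-invariance claim is itself testable; pooled rates average
over realizations.

## Estimating S/V without an oracle

From a sample: OLS of abundance on time gives the slope estimate; the
standard deviation of the residuals gives the variation estimate; their
quotient (using |slope|) is the S/V estimate. The residual sd uses the
plain sample-sd denominator (n − 1) by default, with the regression
convention (n − 2) available (`resid_ddof="regression"`; the difference
is < 4% at n = 30). |slope| makes the ratio an effect-size magnitude:
under a flat protein, noise produces negative fitted slopes half the
time, and they should count toward retention symmetrically. A
noise-free sample has residual sd 0 and the ratio is flagged infinite
rather than raised as an error.

Error distributions (`sv_error_distribution`) report `true − estimate`
over 1000 subsampling events of one large population; the spread at
true S/V = 1 is ≈ 0.35 at n = 100 and ≈ 0.65 at n = 30 — consistent
with the delta-method arithmetic (the slope-standard-error term
`1/(√n · sd(time))` ≈ 0.63 at n = 30 dominates, plus a smaller
residual-sd term). Cutoff filtering (`filter_retention`) uses
1000-cell populations and reports the fraction of events whose
estimated ratio clears the cutoff.

## Replicates and budgets

Per-course rates combine across k independent replicates as `p^k`
(detection required in all k) or as the binomial upper tail
`P(X ≥ n), X ~ Bin(k, p)` (at least n of k); the identical arithmetic
applies to TP and FP rates. `evaluate_budget` looks per-course rates up
in a rate table by exact `(S/V, cells_per_course)` match — no
interpolation between Monte-Carlo grid cells, so a missing cell is a
loud error rather than a silent guess. No within-replicate correlation
is modeled; replicates are assumed fully independent experiments.

## Two-group cohort analysis

For a protein × cell table with two group labels: fold change =
|mean(group A) − mean(group B)| over non-missing values;
within-group variation = sample sd of a designated reference group
(an asymmetry kept deliberately: the reference group plays the role of
the baseline state). Their quotient is an S/V proxy, valid when the
between-state transition is mapped onto a unit pseudotime interval.
Values are assumed already log-transformed; no normalization is
applied. Missing values are ignored per protein with a configurable
`min_obs` threshold (default 3 per group), and dropped-protein counts
are logged — single-cell proteomics matrices are pervasively sparse and
silent dropping would bias the landscape.

The synthetic generator draws per-protein effects and sds (constants or
user-supplied distribution callables), generates Gaussian groups, and
masks entries completely at random. It emulates the *structure* of a
real two-cell-type comparison, not its biology: no correlation between
proteins, no intensity-dependent missingness, no batch structure.
Passing recovery tests on it demonstrates the estimator arithmetic, not
robustness to those real-data features.

## Numerical and degenerate-input choices

- Kernel weights renormalized per grid point (see above); tiny
  bandwidths stay finite.
- `area_between` requires bit-identical grids; refinement from 200 to
  400 points changes normalized areas of smooth curves by < 1%.
- OLS requires ≥ 3 cells and ≥ 2 distinct times; violations raise
  estimation errors naming the condition.
- Populations/samples serialize to CSV at 17 significant digits and
  round-trip bit-exactly (`float_precision="round_trip"` on read).
- Derived seeds are masked to 31 bits.

## Known limitations

- Linear trajectories only; pulse-like or cyclical dynamics would need
  denser sampling and a richer truth model, and are out of scope.
- At very small n, noise-free accuracy is not exactly 1: a subsample
  whose cells all cluster in a narrow time window interpolates to a
  locally flat trajectory that the null fits better (a few percent of
  events at n = 7, ~1 in 10³ at n = 16, negligible by n = 30). This is
  a genuine property of gap-bridging kernel smoothing, consistent with
  the poor reliability of 7-cell designs generally.
- TP-run truth curves use the generative line; applying the rule to
  real data requires the caller to choose reference curves, and the
  reported rates do not cover reference-curve misspecification.
- Rates are Monte-Carlo estimates; at the default protocol the
  replicate spread of a rate is roughly 0.01–0.02, so differences
  smaller than a few points should not be over-interpreted.
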