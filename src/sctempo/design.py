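"""Replicate arithmetic and cell-budget planning.

A "replicate" is an independent repeat of the whole time-course
sampling.  If one time course detects a changing protein with
probability p, requiring detection in all of k replicates succeeds with
probability p**k; requiring at least n of k follows the binomial upper
tail.  Applying the same arithmetic to the per-course false-positive
rate gives the overall FP rate, which is how replication buys down false
positives at the cost of per-course cell density.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

from scipy import stats

from .exceptions import ParameterError
from .power import PowerTable

__all__ = [
    "ReplicateDesign",
    "BudgetScenario",
    "replicate_rate",
    "n_of_k_rate",
    "evaluate_budget",
]

DetectionRule = Literal["all_of_k", "at_least_n_of_k"]


@dataclass(frozen=True)
class ReplicateDesign:
    """Per-course rates plus a detection rule across replicates."""

    per_course_tp: float
    per_course_fp: float
    n_replicates: int
    detection_rule: DetectionRule = "all_of_k"
    n_required: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("per_course_tp", "per_course_fp"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ParameterError(f"{name} must be in [0, 1], got {p}")
        if self.n_replicates < 1:
            raise ParameterError(f"n_replicates must be >= 1, got {self.n_replicates}")
        if self.detection_rule == "at_least_n_of_k":
            if self.n_required is None or not 1 <= self.n_required <= self.n_replicates:
                raise ParameterError(
                    "n_required must satisfy 1 <= n <= n_replicates for at_least_n_of_k"
                )

    def overall_tp(self) -> float:
        return self._combine(self.per_course_tp)

    def overall_fp(self) -> float:
        return self._combine(self.per_course_fp)

    def _combine(self, p: float) -> float:
        if self.detection_rule == "all_of_k":
            return replicate_rate(p, self.n_replicates)
        return n_of_k_rate(p, self.n_required, self.n_replicates)


@dataclass(frozen=True)
class BudgetScenario:
    """One way of spending a cell budget: density vs replication."""

    total_cells: int
    cells_per_course: int
    n_replicates: int
    per_course_tp: float
    per_course_fp: float
    overall_tp: float
    overall_fp: float

    def __post_init__(self) -> None:
        if self.cells_per_course * self.n_replicates > self.total_cells:
            raise ParameterError(
                f"option {self.cells_per_course}x{self.n_replicates} exceeds the "
                f"budget of {self.total_cells} cells"
            )


def replicate_rate(p: float, x: int) -> float:
    """Probability of detection in every one of ``x`` independent replicates: p**x."""
    if not 0 <= p <= 1:
        raise ParameterError(f"p must be in [0, 1], got {p}")
    if int(x) != x or x < 1:
        raise ParameterError(f"x must be a positive integer, got {x}")
    return p ** x


def n_of_k_rate(p: float, n: int, k: int) -> float:
    """Probability of detection in at least ``n`` of ``k`` independent replicates.

    Binomial upper tail: sum_{j=n..k} C(k, j) p**j (1-p)**(k-j).
    """
    if not 0 <= p <= 1:
        raise ParameterError(f"p must be in [0, 1], got {p}")
    if not 1 <= n <= k:
        raise ParameterError(f"need 1 <= n <= k, got n={n}, k={k}")
    # sf(n-1) = P(X >= n)
    return float(stats.binom.sf(n - 1, k, p))


def evaluate_budget(
    total_cells: int,
    options: Sequence[tuple[int, int]],
    rate_source: PowerTable,
    sv: float,
    detection_rule: DetectionRule = "all_of_k",
    n_required: Optional[int] = None,
) -> list[BudgetScenario]:
    """Evaluate (cells_per_course, n_replicates) options against a budget.

    Per-course TP and FP rates are looked up in ``rate_source`` at the
    given S/V — exact (S/V, cells_per_course) lookup only, no
    interpolation between Monte-Carlo grid cells.  Scenarios come back in
    input order so callers can print a side-by-side comparison.
    """
    if not options:
        raise ParameterError("options must be a non-empty list of (cells_per_course, n_replicates)")
    scenarios = []
    for cells_per_course, n_replicates in options:
        if cells_per_course * n_replicates > total_cells:
            raise ParameterError(
                f"option {cells_per_course}x{n_replicates} exceeds the budget of "
                f"{total_cells} cells"
            )
        tp = rate_source.pooled_rate(sv, cells_per_course, "accuracy")
        fp = rate_source.pooled_rate(sv, cells_per_course, "fp_rate")
        design = ReplicateDesign(
            per_course_tp=tp,
            per_course_fp=fp,
            n_replicates=n_replicates,
            detection_rule=detection_rule,
            n_required=n_required,
        )
        scenarios.append(
            BudgetScenario(
                total_cells=total_cells,
                cells_per_course=cells_per_course,
                n_replicates=n_replicates,
                per_course_tp=tp,
                per_course_fp=fp,
                overall_tp=design.overall_tp(),
                overall_fp=design.overall_fp(),
            )
        )
    return scenarios
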