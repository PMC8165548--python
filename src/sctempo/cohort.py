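"""Per-protein effect size and within-group variation from a two-group cohort.

Given a protein x cell table of (log-scale) abundances for exactly two
biological groups — say two cell types — each protein's fold change is
the absolute difference between the group mean abundances, and its
variation is the sample standard deviation within a chosen reference
group.  Their quotient is an S/V proxy: if the transition between the
two states were spread over a unit time course, the fold change would
approximate the slope.  This locates real proteins on the simulated
(S/V, n) design charts.

A synthetic two-group matrix generator with configurable effect sizes,
within-group spreads and completely-at-random missingness makes the
module testable without any external dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Union

import numpy as np
import pandas as pd

from .exceptions import ParameterError

__all__ = [
    "AbundanceMatrix",
    "read_abundance_matrix",
    "effect_table",
    "synth_two_group_matrix",
]

logger = logging.getLogger(__name__)

# a distribution argument is either a constant or a callable (rng, size) -> array
DistLike = Union[float, Callable[[np.random.Generator, int], np.ndarray]]


@dataclass(frozen=True, eq=False)
class AbundanceMatrix:
    """Protein x cell abundance values plus a two-group cell labelling.

    ``values`` is a DataFrame with proteins as rows (index = protein ids)
    and cells as columns; NaN marks missing measurements.
    ``group_labels`` maps each cell id to one of exactly two labels.
    """

    values: pd.DataFrame
    group_labels: pd.Series

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.group_labels.index):
            if set(self.values.columns) != set(self.group_labels.index):
                raise ParameterError("group labels do not cover the matrix's cell columns")
            object.__setattr__(self, "group_labels", self.group_labels.loc[self.values.columns])
        groups = self.group_labels.unique()
        if len(groups) != 2:
            raise ParameterError(f"exactly two groups required, got {sorted(map(str, groups))}")

    @property
    def groups(self) -> tuple[str, str]:
        g = list(pd.unique(self.group_labels))
        return g[0], g[1]


def read_abundance_matrix(
    matrix_path: Union[str, Path],
    groups_path: Union[str, Path],
) -> AbundanceMatrix:
    """Read a protein x cell table and its cell-to-group map.

    The matrix file is CSV or TSV (sniffed from the extension) with a
    ``protein_id`` first column; the group file has two columns
    ``cell_id,group``.
    """
    sep = "\t" if str(matrix_path).endswith((".tsv", ".txt")) else ","
    values = pd.read_csv(matrix_path, sep=sep)
    if values.columns[0] != "protein_id":
        raise ParameterError("matrix file must have 'protein_id' as its first column")
    values = values.set_index("protein_id")
    gsep = "\t" if str(groups_path).endswith((".tsv", ".txt")) else ","
    gmap = pd.read_csv(groups_path, sep=gsep)
    if list(gmap.columns[:2]) != ["cell_id", "group"]:
        raise ParameterError("group file must have columns 'cell_id,group'")
    labels = gmap.set_index("cell_id")["group"]
    return AbundanceMatrix(values=values, group_labels=labels)


def effect_table(
    matrix: AbundanceMatrix,
    reference_group: str,
    min_obs: int = 3,
) -> pd.DataFrame:
    """Per-protein fold change, reference-group sd and S/V proxy.

    fold_change = |mean(reference) - mean(other)| over non-missing
    values; within_group_sd = sample sd of the reference group;
    sv_proxy = fold_change / within_group_sd (inf when the reference
    group is constant — such proteins are reported but should be
    excluded from ratio summaries).  Proteins with fewer than ``min_obs``
    non-missing values in either group are dropped, with the count
    logged.

    Returns a DataFrame indexed by protein id with columns
    ``fold_change, within_group_sd, sv_proxy, n_obs_ref, n_obs_other``.
    """
    labels = matrix.group_labels
    groups = list(pd.unique(labels))
    if reference_group not in groups:
        raise ParameterError(
            f"reference_group {reference_group!r} not among the groups {sorted(map(str, groups))}"
        )
    other_group = next(g for g in groups if g != reference_group)
    ref = matrix.values.loc[:, labels[labels == reference_group].index]
    oth = matrix.values.loc[:, labels[labels == other_group].index]

    n_ref = ref.notna().sum(axis=1)
    n_oth = oth.notna().sum(axis=1)
    keep = (n_ref >= min_obs) & (n_oth >= min_obs)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("effect_table: dropped %d/%d proteins with < %d observations in a group",
                    n_dropped, len(keep), min_obs)

    ref, oth = ref[keep], oth[keep]
    fold = (ref.mean(axis=1) - oth.mean(axis=1)).abs()
    sd = ref.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sv = np.where(sd > 0, fold / sd, np.inf)
    return pd.DataFrame(
        {
            "fold_change": fold,
            "within_group_sd": sd,
            "sv_proxy": sv,
            "n_obs_ref": n_ref[keep],
            "n_obs_other": n_oth[keep],
        }
    )


def _draw(dist: DistLike, rng: np.random.Generator, size: int) -> np.ndarray:
    if callable(dist):
        out = np.asarray(dist(rng, size), dtype=float)
        if out.shape != (size,):
            raise ParameterError(f"distribution callable must return shape ({size},)")
        return out
    return np.full(size, float(dist))


def synth_two_group_matrix(
    n_proteins: int,
    n_cells_per_group: int,
    effect_size_distribution: DistLike = 1.0,
    sd_distribution: DistLike = 0.5,
    missing_rate: float = 0.0,
    seed: int = 0,
    group_names: tuple[str, str] = ("A", "B"),
) -> AbundanceMatrix:
    """Generate a synthetic two-group log-scale abundance matrix.

    Per protein, a true effect (mean shift between groups) and a true
    within-group sd are drawn from the given distributions (a scalar
    means "constant"); values are Gaussian around group means 0 and
    effect.  Entries are masked missing completely at random at
    ``missing_rate``.  Deterministic under ``seed``.
    """
    if n_proteins < 1 or n_cells_per_group < 1:
        raise ParameterError("n_proteins and n_cells_per_group must be positive")
    if not 0 <= missing_rate < 1:
        raise ParameterError(f"missing_rate must be in [0, 1), got {missing_rate}")
    rng = np.random.default_rng(seed)
    effects = _draw(effect_size_distribution, rng, n_proteins)
    sds = _draw(sd_distribution, rng, n_proteins)
    if np.any(sds < 0):
        raise ParameterError("sd_distribution produced negative values")

    n_cells = 2 * n_cells_per_group
    means = np.concatenate(
        [np.zeros((n_proteins, n_cells_per_group)),
         np.tile(effects[:, None], (1, n_cells_per_group))],
        axis=1,
    )
    data = means + rng.normal(0.0, 1.0, size=(n_proteins, n_cells)) * sds[:, None]
    if missing_rate > 0:
        data = np.where(rng.random(data.shape) < missing_rate, np.nan, data)

    cells = [f"{group_names[0]}_{i}" for i in range(n_cells_per_group)] + [
        f"{group_names[1]}_{i}" for i in range(n_cells_per_group)
    ]
    values = pd.DataFrame(data, index=[f"P{i:05d}" for i in range(n_proteins)], columns=cells)
    values.index.name = "protein_id"
    labels = pd.Series(
        [group_names[0]] * n_cells_per_group + [group_names[1]] * n_cells_per_group,
        index=cells,
        name="group",
    )
    labels.index.name = "cell_id"
    return AbundanceMatrix(values=values, group_labels=labels)
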