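"""Figure helpers mirroring the standard outputs of the design workflows."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .svtools import RetentionResult, SVErrorSummary

PathLike = Union[str, Path]


def plot_rate_curves(df: pd.DataFrame, path: PathLike) -> None:
    """Rate vs n_sample, one line per (rate_kind, S/V or slope/noise cell)."""
    kinds = df["rate_kind"].unique()
    fig, axes = plt.subplots(1, len(kinds), figsize=(5 * len(kinds), 4), squeeze=False)
    for ax, kind in zip(axes[0], kinds):
        sub = df[df["rate_kind"] == kind]
        for (sv, slope, sd), grp in sub.groupby(["sv", "slope", "noise_sd"]):
            grp = grp.sort_values("n_sample")
            ax.errorbar(grp["n_sample"], grp["rate"], yerr=grp["spread"],
                        marker="o", capsize=3, label=f"S/V={sv:g} ({slope:g}/{sd:g})")
        ax.set_xlabel("cells sampled per time course")
        ax.set_ylabel("TP rate" if kind == "accuracy" else "FP rate")
        ax.set_ylim(0, 1.02)
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_sv_error_density(summaries: Sequence[SVErrorSummary], path: PathLike) -> None:
    """Density of (true - estimated) S/V, one curve per sample size."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for s in summaries:
        ax.hist(s.errors, bins=60, density=True, histtype="step",
                label=f"n={s.n_sample} (sd={s.sd_error:.2f})")
    ax.set_xlabel("true S/V − estimated S/V")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_retention(results: Sequence[RetentionResult], path: PathLike) -> None:
    """Percent of subsampling events kept vs true S/V."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar([str(r.true_sv) for r in results],
           [100 * r.fraction_retained for r in results], color="steelblue")
    ax.set_xlabel("true S/V")
    ax.set_ylabel("% of events retained")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_effect_scatter(effect_df: pd.DataFrame, path: PathLike) -> None:
    """Fold change vs within-group variation for each protein."""
    finite = effect_df[effect_df["within_group_sd"] > 0]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(finite["within_group_sd"], finite["fold_change"], s=6, alpha=0.4)
    lim = max(finite["within_group_sd"].max(), finite["fold_change"].max())
    ax.plot([0, lim], [0, lim], "k--", lw=1, label="fold change = variation (S/V = 1)")
    ax.set_xlabel("within-group sd")
    ax.set_ylabel("|fold change|")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
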