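"""Descriptive tables and forest plots."""

from __future__ import annotations

import math
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .weights import WeightVector, weighted_proportions

#: covariates reported in the descriptive table, in presentation order
SUMMARY_VARIABLES = (
    "age",
    "education",
    "composition",
    "employment",
    "income",
    "home_location",
    "car",
)


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves away from zero (table style)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def summarize_sample(
    households: pd.DataFrame,
    weights: Optional[WeightVector | np.ndarray] = None,
    variables: Sequence[str] = SUMMARY_VARIABLES,
) -> pd.DataFrame:
    """Descriptive table: per covariate level, raw n, raw % and weighted %.

    Raw percentages are ``100 * n / N`` rounded half-up to integers, so each
    variable's column sums to 100 up to rounding.
    """
    if len(households) == 0:
        raise ValueError("need at least one household")
    N = len(households)
    rows = []
    for var in variables:
        if var not in households.columns:
            continue
        counts = households[var].astype(str).value_counts()
        wprops = (
            weighted_proportions(households, weights, var)
            if weights is not None
            else None
        )
        for level, n in counts.sort_index().items():
            row = {
                "variable": var,
                "level": level,
                "n": int(n),
                "raw_pct": round_half_up(100.0 * n / N),
            }
            if wprops is not None:
                row["weighted_pct"] = round_half_up(100.0 * wprops[level])
            rows.append(row)
    return pd.DataFrame(rows)


def plot_effects(
    estimates: pd.DataFrame,
    path=None,
    title: str = "",
):
    """Paired forest plot of odds ratios, home buffer vs activity space.

    Accepts the tidy estimates table (possibly both area kinds stacked);
    pure presentation — every number plotted comes from the table.
    """
    fig, ax = plt.subplots(figsize=(7, max(2, 0.35 * max(len(estimates), 1))))
    if len(estimates) == 0:
        ax.set_title(title or "no estimates")
        if path:
            fig.savefig(path, dpi=100)
            plt.close(fig)
        return fig
    kinds = (
        list(estimates["area_kind"].unique())
        if "area_kind" in estimates
        else ["estimates"]
    )
    offsets = np.linspace(-0.15, 0.15, len(kinds))
    colors = {k: c for k, c in zip(kinds, ("tab:blue", "tab:orange", "tab:green"))}
    labels = [
        f"{r['covariate']}={r['level']} ({r['contrast']})"
        for _, r in estimates.drop_duplicates(
            subset=["covariate", "level", "contrast"]
        ).iterrows()
    ]
    ypos = {lab: i for i, lab in enumerate(labels)}
    for kind, off in zip(kinds, offsets):
        sub = (
            estimates[estimates["area_kind"] == kind]
            if "area_kind" in estimates
            else estimates
        )
        for _, r in sub.iterrows():
            lab = f"{r['covariate']}={r['level']} ({r['contrast']})"
            y = ypos[lab] + off
            ax.plot(
                [r["ci_low"], r["ci_high"]], [y, y], color=colors[kind], lw=1.2
            )
            ax.plot(
                [r["or_"]], [y], "o", color=colors[kind], ms=4,
                label=kind if lab == labels[0] else None,
            )
    ax.axvline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(range(len(labels)))
    ax.set_yticklabels(labels, fontsize=7)
    ax.set_xlabel("odds ratio (95% CI)")
    ax.set_xscale("log")
    if title:
        ax.set_title(title)
    handles, labs = ax.get_legend_handles_labels()
    if handles:
        ax.legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
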