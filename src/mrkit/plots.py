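"""Minimal scatter (per-variant) and forest (across-trait) rendering."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def scatter_plot(variant_table: pd.DataFrame, path, title: str = "") -> None:
    """SNP-outcome vs SNP-exposure associations with 95% CIs and the
    fitted causal slope through the origin."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(
        variant_table["beta_exposure"],
        variant_table["beta_outcome"],
        yerr=1.959964 * variant_table["se_outcome"],
        xerr=1.959964 * variant_table["se_exposure"],
        fmt="o", ms=4, lw=0.8, color="0.3", ecolor="0.6",
    )
    slope = float(variant_table["slope"].iloc[0])
    xs = np.array([min(0.0, variant_table["beta_exposure"].min()),
                   max(0.0, variant_table["beta_exposure"].max())])
    ax.plot(xs, slope * xs, color="crimson", lw=1.5)
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.set_xlabel("SNP effect on exposure")
    ax.set_ylabel("SNP effect on outcome (log OR)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def forest_plot(rows: pd.DataFrame, path) -> None:
    """One OR (95% CI) marker per trait, log-scaled x axis."""
    fig, ax = plt.subplots(figsize=(5, 0.6 * len(rows) + 1.2))
    y = np.arange(len(rows))[::-1]
    or_ = rows["OR"].to_numpy()
    lo = rows["OR_low"].to_numpy()
    hi = rows["OR_high"].to_numpy()
    ax.errorbar(
        or_, y, xerr=[or_ - lo, hi - or_],
        fmt="s", color="0.2", ecolor="0.4", capsize=2,
    )
    ax.axvline(1.0, color="0.7", lw=0.8, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels(rows["trait"])
    ax.set_xscale("log")
    ax.set_xlabel("Odds ratio (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
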