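"""Minimal diagnostic plots (matplotlib, Agg-safe).

These are working diagnostics, not publication graphics: every analysis
function in the package emits tidy tables from which any plotting layer can
draw; the helpers here render quick PNGs for sanity checks.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .data import LongitudinalDataset, summarize_by_group
from .effects import BandCurve, QuantileDots

__all__ = [
    "plot_group_curves",
    "plot_quantile_dots",
    "plot_band_curve",
    "plot_sa_trace",
    "plot_forest",
    "plot_heatmap",
]


def _save(fig, path):
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_group_curves(ds: LongitudinalDataset, path) -> None:
    """Mean +/- SE growth curve per condition."""
    summ = summarize_by_group(ds)
    fig, ax = plt.subplots(figsize=(6, 4))
    for cond, sub in summ.groupby("condition"):
        ax.errorbar(sub["time"], sub["mean"], yerr=sub["se"], label=cond, capsize=2)
    ax.set_xlabel(ds.time_name)
    ax.set_ylabel(ds.value_name)
    ax.legend()
    _save(fig, path)


def plot_quantile_dots(dots: QuantileDots, path, threshold: float = 0.0) -> None:
    """Stacked-dot rendering of K posterior quantiles, split at a threshold."""
    fig, ax = plt.subplots(figsize=(6, 2.8))
    above = dots.dots > threshold
    ax.plot(dots.dots[~above], np.zeros((~above).sum()), "o", ms=4, alpha=0.6)
    ax.plot(dots.dots[above], np.zeros(above.sum()), "o", ms=4, alpha=0.6)
    ax.axvline(threshold, color="k", lw=0.8)
    ax.set_yticks([])
    ax.set_xlabel("effect size")
    _save(fig, path)


def plot_band_curve(curve: BandCurve, path) -> None:
    """Median difference curve with nested central bands."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for lev in sorted(curve.levels, reverse=True):
        ax.fill_between(
            curve.times, curve.lower[lev], curve.upper[lev],
            alpha=0.25, label=f"{int(lev * 100)}%",
        )
    ax.plot(curve.times, curve.center, color="k")
    ax.axhline(0.0, color="k", lw=0.6, ls="--")
    ax.set_xlabel("time")
    ax.set_ylabel("difference")
    ax.legend()
    _save(fig, path)


def plot_sa_trace(trace: pd.DataFrame, path) -> None:
    """Four randomization metric sums vs iteration."""
    from .randomize import METRIC_NAMES

    fig, axes = plt.subplots(2, 2, figsize=(8, 6), sharex=True)
    for ax, name in zip(axes.ravel(), METRIC_NAMES):
        ax.plot(trace["iteration"], trace[name])
        ax.set_title(name)
    for ax in axes[1]:
        ax.set_xlabel("iteration")
    _save(fig, path)


def plot_forest(table: pd.DataFrame, path) -> None:
    """Forest plot of ranked endpoint contrasts (mean and interval)."""
    fig, ax = plt.subplots(figsize=(6, 0.3 * len(table) + 1.5))
    ypos = np.arange(len(table))
    ax.hlines(ypos, table["lower"], table["upper"], lw=2, alpha=0.7)
    ax.plot(table["mean"], ypos, "o", color="k", ms=4)
    ax.axvline(0.0, color="k", lw=0.6, ls="--")
    ax.set_yticks(ypos)
    ax.set_yticklabels(table["condition"])
    ax.set_xlabel("contrast vs control")
    _save(fig, path)


def plot_heatmap(table: pd.DataFrame, path) -> None:
    """Condition x time heatmap of mean differences vs control."""
    wide = table.pivot(index="condition", columns="time", values="mean_difference")
    fig, ax = plt.subplots(figsize=(7, 0.3 * len(wide) + 1.5))
    im = ax.imshow(wide.to_numpy(), aspect="auto", cmap="coolwarm")
    ax.set_yticks(range(len(wide)))
    ax.set_yticklabels(wide.index)
    ax.set_xticks(range(len(wide.columns)))
    ax.set_xticklabels([f"{t:g}" for t in wide.columns], rotation=90, fontsize=7)
    fig.colorbar(im, ax=ax, label="mean difference")
    _save(fig, path)
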