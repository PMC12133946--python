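"""Effect-size summaries computed from posterior draws.

All operations here are pure functions of an existing draw matrix — no
re-sampling.  The primary effect size for linear-time models is the slope
difference between two conditions (the time x condition interaction); for
spline models effects are expressed as predicted-difference curves over a
time grid and endpoint contrasts (difference-in-differences of predicted
means, a log fold-change on log2-scale screen data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes import PosteriorDraws, posterior_predict_mean
from .design import DesignMatrices

__all__ = [
    "ContrastDraws",
    "QuantileDots",
    "BandCurve",
    "slope_difference_draws",
    "quantile_dots",
    "prob_greater",
    "predicted_difference_curve",
    "endpoint_contrast",
    "rank_conditions",
    "difference_heatmap_table",
]


@dataclass
class ContrastDraws:
    """Per-draw values of a labeled contrast (minuend minus subtrahend)."""

    label: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()


@dataclass
class QuantileDots:
    """K equal-probability posterior quantiles (each dot = 1/K of mass)."""

    probs: np.ndarray
    dots: np.ndarray

    @property
    def K(self) -> int:
        return len(self.dots)

    def fraction_above(self, threshold: float = 0.0) -> float:
        return float(np.mean(self.dots > threshold))


@dataclass
class BandCurve:
    """Median difference curve with nested central uncertainty bands."""

    times: np.ndarray
    center: np.ndarray
    levels: tuple
    lower: dict  # level -> array over times
    upper: dict

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.times):
            for lev in self.levels:
                rows.append(
                    {
                        "time": t,
                        "level": lev,
                        "center": self.center[i],
                        "lower": self.lower[lev][i],
                        "upper": self.upper[lev][i],
                    }
                )
        return pd.DataFrame(rows)


def _slope_draws(draws: PosteriorDraws, design: DesignMatrices, cond: str) -> np.ndarray:
    if len(design.time_colnames) != 1:
        raise ValueError(
            "slope differences need a linear-time model; "
            "use predicted_difference_curve for spline fits"
        )
    if cond not in design.conditions:
        raise ValueError(f"unknown condition {cond!r}")
    s = draws.param("time").copy()
    if cond != design.reference:
        s += draws.param(f"time:cond[{cond}]")
    return s


def slope_difference_draws(
    draws: PosteriorDraws, design: DesignMatrices, condA: str, condB: str
) -> ContrastDraws:
    """Per-draw growth-rate difference slope(condA) - slope(condB)."""
    return ContrastDraws(
        label=f"{condA} - {condB}",
        values=_slope_draws(draws, design, condA) - _slope_draws(draws, design, condB),
    )


def quantile_dots(c: ContrastDraws, K: int = 100, method: str = "linear") -> QuantileDots:
    """K empirical quantiles at probabilities (i - 0.5)/K.

    With K = 100, each dot carries 1% of posterior mass, so counting dots
    above zero reads directly as a posterior probability (98 of 100 dots
    above 0 = 98%).  ``method`` is any numpy quantile method; with
    ``method="nearest"`` and K equal to the number of draws the dots are
    exactly the sorted draws.
    """
    if len(c.values) < K:
        raise ValueError(f"need at least K={K} draws, got {len(c.values)}")
    probs = (np.arange(1, K + 1) - 0.5) / K
    return QuantileDots(probs=probs, dots=np.quantile(c.values, probs, method=method))


def prob_greater(c: ContrastDraws, threshold: float = 0.0) -> float:
    """Posterior probability that the contrast exceeds the threshold."""
    if len(c.values) == 0:
        raise ValueError("empty contrast draws")
    return float(np.mean(c.values > threshold))


def _predicted_means(
    draws: PosteriorDraws, design: DesignMatrices, cond: str, times
) -> np.ndarray:
    X = design.population_matrix([cond], list(times))
    return posterior_predict_mean(draws, design, X)


def predicted_difference_curve(
    draws: PosteriorDraws,
    design: DesignMatrices,
    condA: str,
    condB: str,
    time_grid,
    levels=(0.25, 0.5, 0.8, 0.95),
) -> BandCurve:
    """Population-level predicted-mean difference condA - condB over a grid.

    Per time: the posterior median of the difference plus central intervals
    at each requested level (default 25/50/80/95%).  Times outside the
    observed range trigger a warning but are computed.
    """
    import warnings

    tg = np.asarray(list(time_grid), dtype=float)
    lo, hi = design.time_range
    if tg.size and (tg.min() < lo or tg.max() > hi):
        warnings.warn("time grid extends beyond the observed time range (extrapolating)")
    diff = _predicted_means(draws, design, condA, tg) - _predicted_means(
        draws, design, condB, tg
    )
    levels = tuple(sorted(levels))
    lower, upper = {}, {}
    for lev in levels:
        a = (1.0 - lev) / 2.0
        lower[lev] = np.quantile(diff, a, axis=0)
        upper[lev] = np.quantile(diff, 1.0 - a, axis=0)
    return BandCurve(
        times=tg, center=np.median(diff, axis=0), levels=levels, lower=lower, upper=upper
    )


def endpoint_contrast(
    draws: PosteriorDraws,
    design: DesignMatrices,
    c1: str,
    c0: str,
    t0: float,
    t1: float,
) -> ContrastDraws:
    """Difference-in-differences of predicted means, normalized to t0:

        (M[t1,c1] - M[t1,c0]) - (M[t0,c1] - M[t0,c0])

    On log2-scale screen data this is the log fold-change of condition c1
    relative to comparator c0 over the window [t0, t1].
    """
    if not t0 < t1:
        raise ValueError("need t0 < t1")
    m1 = _predicted_means(draws, design, c1, [t0, t1])
    m0 = _predicted_means(draws, design, c0, [t0, t1])
    vals = (m1[:, 1] - m0[:, 1]) - (m1[:, 0] - m0[:, 0])
    return ContrastDraws(label=f"{c1} - {c0} [{t0}->{t1}]", values=vals)


def rank_conditions(
    draws: PosteriorDraws,
    design: DesignMatrices,
    control: str,
    t0: float,
    t1: float,
    level: float = 0.95,
) -> pd.DataFrame:
    """Screen-wide ranking of conditions by endpoint contrast vs control.

    One row per non-control condition with the posterior mean contrast, a
    central interval at ``level`` and P(contrast > 0), sorted ascending by
    mean (forest-plot order).
    """
    if control not in design.conditions:
        raise ValueError(f"control condition {control!r} not present")
    a = (1.0 - level) / 2.0
    rows = []
    for cond in design.conditions:
        if cond == control:
            continue
        c = endpoint_contrast(draws, design, cond, control, t0, t1)
        rows.append(
            {
                "condition": cond,
                "mean": float(np.mean(c.values)),
                "lower": float(np.quantile(c.values, a)),
                "upper": float(np.quantile(c.values, 1.0 - a)),
                "prob_gt_0": prob_greater(c),
            }
        )
    return (
        pd.DataFrame(rows).sort_values("mean", kind="mergesort").reset_index(drop=True)
    )


def difference_heatmap_table(
    draws: PosteriorDraws, design: DesignMatrices, control: str, time_grid
) -> pd.DataFrame:
    """Tidy (condition, time, mean_difference) table of average differences
    of predicted means vs control over a time grid (heatmap input).

    Cells hold the posterior MEAN difference; the companion curve functions
    use the median as their center.
    """
    if control not in design.conditions:
        raise ValueError(f"control condition {control!r} not present")
    tg = np.asarray(list(time_grid), dtype=float)
    ctrl = _predicted_means(draws, design, control, tg)
    rows = []
    for cond in design.conditions:
        if cond == control:
            continue
        diff = _predicted_means(draws, design, cond, tg) - ctrl
        means = diff.mean(axis=0)
        for t, m in zip(tg, means):
            rows.append({"condition": cond, "time": t, "mean_difference": float(m)})
    return pd.DataFrame(rows)
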