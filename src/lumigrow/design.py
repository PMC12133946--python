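"""Model specification, design matrices, and default weakly-informative priors.

The working model for a log-scale growth measurement is

    y = alpha + X beta + Z b + eps,      eps ~ N(0, sigma^2 I)

where X holds a time basis (linear, or a linear spline in the truncated-power
basis), reference-coded condition indicators and their interactions with the
time basis, and Z is the unit-indicator matrix for random intercepts b.

Default priors follow the weakly-informative autoscaling convention:
beta_k ~ N(0, 2.5 s_y / s_{x_k}), alpha ~ N(m_y, 2.5 s_y) with covariates
centered for the intercept prior, and sigma ~ Exponential(rate 1/s_y).  The
random-intercept scale sigma_b gets the same exponential prior family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import DataError, LongitudinalDataset

__all__ = [
    "ModelSpec",
    "DesignMatrices",
    "PriorSpec",
    "build_design",
    "linear_spline_basis",
    "default_priors",
]


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect and grouping structure of the growth model.

    ``spline_knots`` empty means a single linear time trend; otherwise a
    linear spline with those interior knots.  ``reference`` fixes the
    reference condition for dummy coding (alphabetically first if None).
    """

    spline_knots: tuple = ()
    reference: str | None = None
    grouping: str = "unit_id"

    def __post_init__(self):
        knots = tuple(float(k) for k in self.spline_knots)
        if list(knots) != sorted(knots):
            raise ValueError("spline knots must be sorted ascending")
        object.__setattr__(self, "spline_knots", knots)


@dataclass
class DesignMatrices:
    """Dense design matrices plus label bookkeeping.

    ``X`` includes the all-ones intercept column first; ``column_map`` maps
    each X column label to its index.  ``Z`` has one indicator column per
    unit (each row sums to 1), labelled by ``unit_labels``.
    """

    X: np.ndarray
    Z: np.ndarray
    y: np.ndarray
    column_map: dict[str, int]
    unit_labels: list[str]
    conditions: list[str]
    reference: str
    time_colnames: list[str]  # labels of the time-basis columns
    spline_knots: tuple = ()
    time_range: tuple = (0.0, 0.0)

    @property
    def labels(self) -> list[str]:
        return list(self.column_map)

    def time_basis(self, times: np.ndarray) -> np.ndarray:
        return linear_spline_basis(np.asarray(times, dtype=float), list(self.spline_knots))

    def row_for(self, condition: str, time: float) -> np.ndarray:
        """Fixed-effect row (population level) for a condition at a time."""
        if condition not in self.conditions:
            raise ValueError(f"unknown condition {condition!r}")
        row = np.zeros(self.X.shape[1])
        row[0] = 1.0
        tb = self.time_basis(np.array([time]))[0]
        for j, tname in enumerate(self.time_colnames):
            row[self.column_map[tname]] = tb[j]
        if condition != self.reference:
            row[self.column_map[f"cond[{condition}]"]] = 1.0
            for tname in self.time_colnames:
                row[self.column_map[f"{tname}:cond[{condition}]"]] = tb[
                    self.time_colnames.index(tname)
                ]
        return row

    def population_matrix(self, conditions, times) -> np.ndarray:
        """Stack of row_for over the product of conditions x times (row-major)."""
        rows = [self.row_for(c, t) for c in conditions for t in times]
        return np.vstack(rows)


@dataclass
class PriorSpec:
    """Normal priors on (alpha, beta), exponential priors on (sigma, sigma_b)."""

    alpha_mean: float
    alpha_sd: float
    beta_sd: np.ndarray  # per non-intercept coefficient, prior mean 0
    sigma_rate: float
    sigma_b_rate: float
    x_center: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        self.beta_sd = np.asarray(self.beta_sd, dtype=float)
        if self.alpha_sd <= 0 or self.sigma_rate <= 0 or self.sigma_b_rate <= 0:
            raise ValueError("prior scales and rates must be strictly positive")
        if (self.beta_sd <= 0).any():
            raise ValueError("beta prior sds must be strictly positive")


def linear_spline_basis(times: np.ndarray, knots) -> np.ndarray:
    """Truncated-power linear spline basis: [t, (t-k1)_+, (t-k2)_+, ...].

    With no knots this is the single column t.  Knots must be sorted and lie
    strictly inside the range of ``times``.
    """
    t = np.asarray(times, dtype=float)
    knots = [float(k) for k in knots]
    if knots != sorted(knots):
        raise ValueError("knots must be sorted ascending")
    if t.size and knots:
        lo, hi = t.min(), t.max()
        for k in knots:
            if not (lo < k < hi):
                raise ValueError(f"knot {k} outside the open time range ({lo}, {hi})")
    cols = [t] + [np.maximum(t - k, 0.0) for k in knots]
    return np.column_stack(cols)


def build_design(ds: LongitudinalDataset, spec: ModelSpec | None = None) -> DesignMatrices:
    """Render the growth-model formula into dense design matrices.

    X = [1 | time basis | condition dummies | time basis x condition dummies]
    with reference-level dummy coding; Z = unit indicators.  Column labels
    are deterministic (e.g. ``time``, ``cond[E2]``, ``time:cond[E2]``).
    """
    spec = spec or ModelSpec()
    df = ds.df.sort_values(["unit_id", "time"], kind="mergesort").reset_index(drop=True)
    conditions = sorted(df["condition"].unique())
    reference = spec.reference or conditions[0]
    if reference not in conditions:
        raise DataError(f"reference condition {reference!r} not present")
    counts = df["condition"].value_counts()
    singletons = [c for c in conditions if counts[c] == 1]
    if singletons:
        warnings.warn(f"condition(s) {singletons} have a single observation")

    t = df["time"].to_numpy(dtype=float)
    TB = linear_spline_basis(t, list(spec.spline_knots))
    time_colnames = ["time"] + [f"time_k{k:g}" for k in spec.spline_knots]

    cols = [np.ones(len(df))]
    labels = ["(Intercept)"]
    for j, tname in enumerate(time_colnames):
        cols.append(TB[:, j])
        labels.append(tname)
    others = [c for c in conditions if c != reference]
    for c in others:
        cols.append((df["condition"] == c).to_numpy(dtype=float))
        labels.append(f"cond[{c}]")
    for c in others:
        ind = (df["condition"] == c).to_numpy(dtype=float)
        for j, tname in enumerate(time_colnames):
            cols.append(TB[:, j] * ind)
            labels.append(f"{tname}:cond[{c}]")
    X = np.column_stack(cols)

    units = sorted(df["unit_id"].unique())
    uidx = {u: i for i, u in enumerate(units)}
    Z = np.zeros((len(df), len(units)))
    Z[np.arange(len(df)), [uidx[u] for u in df["unit_id"]]] = 1.0

    return DesignMatrices(
        X=X,
        Z=Z,
        y=df["value"].to_numpy(dtype=float),
        column_map={lab: i for i, lab in enumerate(labels)},
        unit_labels=units,
        conditions=conditions,
        reference=reference,
        time_colnames=time_colnames,
        spline_knots=tuple(spec.spline_knots),
        time_range=(float(t.min()), float(t.max())) if len(t) else (0.0, 0.0),
    )


def default_priors(
    design: DesignMatrices,
    family: str = "gaussian",
    alpha_override: tuple[float, float] | None = None,
) -> PriorSpec:
    """Weakly-informative autoscaled priors for the Gaussian growth model.

    beta_k ~ N(0, 2.5 s_y / s_{x_k});  alpha ~ N(mean(y), 2.5 s_y) with
    covariates centered when forming the intercept prior;  sigma and sigma_b
    ~ Exponential(rate 1/s_y).  ``alpha_override = (mean, sd)`` replaces the
    intercept prior verbatim (e.g. N(7, 2) for log10 total-flux data where 7
    is a typical treatment-start threshold).
    """
    if family != "gaussian":
        raise ValueError("only the gaussian family is supported")
    y = design.y
    s_y = float(np.std(y, ddof=1))
    if not np.isfinite(s_y) or s_y <= 0:
        raise DataError("response has zero variance; priors cannot be autoscaled")
    Xc = design.X[:, 1:]
    s_x = np.std(Xc, axis=0, ddof=1)
    if (s_x <= 0).any():
        bad = [design.labels[1 + i] for i in np.nonzero(s_x <= 0)[0]]
        raise DataError(f"constant covariate column(s) {bad}; cannot autoscale priors")
    beta_sd = 2.5 * s_y / s_x
    if alpha_override is not None:
        a_mean, a_sd = float(alpha_override[0]), float(alpha_override[1])
    else:
        a_mean, a_sd = float(np.mean(y)), 2.5 * s_y
    return PriorSpec(
        alpha_mean=a_mean,
        alpha_sd=a_sd,
        beta_sd=beta_sd,
        sigma_rate=1.0 / s_y,
        sigma_b_rate=1.0 / s_y,
        x_center=Xc.mean(axis=0),
    )
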