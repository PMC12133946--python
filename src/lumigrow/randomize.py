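"""Pretreatment randomization of experimental units by simulated annealing.

Before treatment starts, units (or their parent animals) are split into
groups whose pretreatment growth kinetics match as closely as possible.
Times are first shifted so the last measurement sits at time 0, making each
group's pooled regression intercept the average of its last measurements.
The annealer then minimizes the sum of pairwise absolute differences of the
group intercepts and slopes (the two standard errors are traced as
diagnostics): each iteration regenerates a fresh random balanced split and
accepts worsening moves with probability exp(-cost/temperature) under a
geometric cooling schedule (temperature_k = T0 * alpha^k, alpha = 0.5,
T0 = 1, 100 iterations by default).  An exhaustive enumerator provides the
exact optimum for small cohorts.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .data import DataError, LongitudinalDataset

__all__ = [
    "SplitAssignment",
    "AnnealedGroupSplitter",
    "shift_times",
    "group_metrics",
    "pairwise_metric_sums",
    "sa_split",
    "brute_force_split",
    "exclusion_report",
]

METRIC_NAMES = ("intercept_sum", "slope_sum", "se_intercept_sum", "se_slope_sum")


@dataclass
class SplitAssignment:
    """Assignment of randomizable items (units or parents) to groups."""

    item_to_group: dict  # item id -> group label
    unit_to_group: dict  # unit id -> group label
    n_groups: int
    level: str = "unit"
    blocks_respected: bool = False

    def groups(self) -> dict:
        out: dict[str, list] = {}
        for item, g in self.item_to_group.items():
            out.setdefault(g, []).append(item)
        return {g: sorted(v) for g, v in sorted(out.items())}

    def to_frame(self, ds: LongitudinalDataset) -> pd.DataFrame:
        tab = ds.unit_table()
        tab["group"] = tab["unit_id"].map(self.unit_to_group)
        return tab


def shift_times(ds: LongitudinalDataset) -> LongitudinalDataset:
    """Shift all times so the global maximum becomes 0 (idempotent)."""
    if ds.n_records == 0:
        raise DataError("empty dataset")
    df = ds.df.copy()
    df["time"] = df["time"] - df["time"].max()
    return dataclasses.replace(ds, df=df, load_report=ds.load_report.__class__())


def _pooled_ols(t: np.ndarray, v: np.ndarray):
    """Pooled OLS of value on time: (slope, intercept, se_slope, se_intercept)."""
    X = sm.add_constant(np.asarray(t, dtype=float))
    res = sm.OLS(np.asarray(v, dtype=float), X).fit()
    icpt, slope = res.params
    se_icpt, se_slope = res.bse
    # saturated two-point/three-obs fits can yield nan ses; treat exact fits as 0
    if not np.isfinite(se_icpt):
        se_icpt = 0.0
    if not np.isfinite(se_slope):
        se_slope = 0.0
    return float(slope), float(icpt), float(se_slope), float(se_icpt)


def group_metrics(ds_shifted: LongitudinalDataset, unit_to_group: dict) -> pd.DataFrame:
    """Per-group pooled OLS metrics on shifted time.

    Returns one row per group: ``group, slope, intercept, se_slope,
    se_intercept``.  Each group needs at least 2 distinct times and 3
    measurements; a degenerate group raises :class:`DataError` naming it.
    """
    df = ds_shifted.df
    g = df["unit_id"].map(unit_to_group)
    if g.isna().any():
        missing = sorted(df.loc[g.isna(), "unit_id"].unique())
        raise DataError(f"units with no group assignment: {missing}")
    rows = []
    for grp, sub in df.groupby(g.rename("group")):
        if sub["time"].nunique() < 2 or len(sub) < 3:
            raise DataError(f"group {grp!r} is degenerate (needs >=2 times, >=3 records)")
        slope, icpt, se_s, se_i = _pooled_ols(sub["time"].to_numpy(), sub["value"].to_numpy())
        rows.append(
            {"group": grp, "slope": slope, "intercept": icpt,
             "se_slope": se_s, "se_intercept": se_i}
        )
    return pd.DataFrame(rows).sort_values("group").reset_index(drop=True)


def pairwise_metric_sums(metrics: pd.DataFrame) -> dict:
    """Sums over group pairs i<j of |metric_i - metric_j| for the four metrics.

    Absolute differences make the minimization target well-defined for any
    group labelling (a signed sum could be driven arbitrarily negative).
    """
    if len(metrics) < 2:
        raise DataError("need at least 2 groups")
    out = {}
    for name, col in zip(
        METRIC_NAMES, ("intercept", "slope", "se_intercept", "se_slope")
    ):
        v = metrics[col].to_numpy()
        out[name] = float(sum(abs(a - b) for i, a in enumerate(v) for b in v[i + 1:]))
    return out


def _items_table(ds: LongitudinalDataset, level: str, block_column) -> pd.DataFrame:
    """One row per randomizable item with its block label and member units."""
    tab = ds.unit_table()
    if level == "parent":
        if (tab["parent_id"] == "").any():
            raise DataError("parent-level randomization requires parent_id for every unit")
        key = "parent_id"
    elif level == "unit":
        key = "unit_id"
    else:
        raise ValueError("level must be 'unit' or 'parent'")
    if block_column is None:
        tab = tab.assign(_block="")
    else:
        if block_column not in tab.columns:
            raise DataError(f"unknown block column {block_column!r}")
        tab = tab.assign(_block=tab[block_column])
        nblk = tab.groupby(key)["_block"].nunique()
        if (nblk > 1).any():
            raise DataError("items spanning multiple blocks cannot be block-randomized")
    rows = [
        {"item": item, "block": sub["_block"].iloc[0], "units": sorted(sub["unit_id"])}
        for item, sub in tab.groupby(key)
    ]
    return pd.DataFrame(rows).sort_values("item").reset_index(drop=True)


def _group_labels(n_groups: int) -> list[str]:
    return [f"cluster_{i + 1}" for i in range(n_groups)]


def _initial_split(items: pd.DataFrame, n_groups: int, rng: np.random.Generator) -> dict:
    """Random balanced split, stratified within block levels (round-robin deal)."""
    labels = _group_labels(n_groups)
    assign = {}
    offset = rng.integers(n_groups)
    for _, sub in items.groupby("block"):
        idx = rng.permutation(len(sub))
        for pos, i in enumerate(idx):
            assign[sub["item"].iloc[i]] = labels[(pos + offset) % n_groups]
        offset = (offset + len(sub)) % n_groups
    return assign


def _unit_map(items: pd.DataFrame, assign: dict) -> dict:
    out = {}
    for _, row in items.iterrows():
        for u in row["units"]:
            out[u] = assign[row["item"]]
    return out


def _objective(sums: dict) -> tuple:
    return (sums["intercept_sum"], sums["slope_sum"])


def sa_split(
    ds: LongitudinalDataset,
    n_groups: int = 2,
    n_iterations: int = 100,
    alpha: float = 0.5,
    temperature0: float = 1.0,
    seed: int = 0,
    block_column: str | None = None,
    level: str = "unit",
) -> tuple[SplitAssignment, pd.DataFrame]:
    """Simulated-annealing balanced split minimizing kinetic imbalance.

    Each iteration regenerates a fresh random balanced split (stratified
    within blocks when blocking) as the proposal.  A proposal replaces the
    current split outright when BOTH the intercept and the slope pairwise
    sums decrease; otherwise it is accepted with probability
    exp(-cost/temperature) where
    cost = (new_intercept_sum - old_intercept_sum)/new_intercept_sum and the
    temperature cools geometrically (T_k = T0 * alpha^k).  The best split
    examined anywhere in the run, by lexicographic (intercept sum, slope
    sum), is returned together with the per-iteration trace of all four
    metric sums.
    """
    rng = np.random.default_rng(seed)
    dss = shift_times(ds)
    items = _items_table(dss, level, block_column)
    if len(items) < n_groups:
        raise DataError(f"only {len(items)} items for {n_groups} groups")
    if block_column is not None:
        small = items.groupby("block").size()
        # blocks smaller than n_groups cannot be dealt one item per group
        if (small < n_groups).any():
            bad = small[small < n_groups].index.tolist()
            raise DataError(f"block(s) {bad} smaller than n_groups; balanced blocking infeasible")

    assign = _initial_split(items, n_groups, rng)
    sums = pairwise_metric_sums(group_metrics(dss, _unit_map(items, assign)))
    best_assign, best_obj = dict(assign), _objective(sums)

    trace_rows = []
    temperature = float(temperature0)
    for k in range(1, n_iterations + 1):
        accepted = False
        new_assign = _initial_split(items, n_groups, rng)
        try:
            new_sums = pairwise_metric_sums(
                group_metrics(dss, _unit_map(items, new_assign))
            )
        except DataError:
            new_sums = None  # degenerate proposal: reject, keep going
        if new_sums is not None:
            if _objective(new_sums) < best_obj:  # best over everything examined
                best_assign, best_obj = dict(new_assign), _objective(new_sums)
            better_both = (
                new_sums["intercept_sum"] < sums["intercept_sum"]
                and new_sums["slope_sum"] < sums["slope_sum"]
            )
            if better_both:
                accepted = True
            else:
                old_g, new_g = sums["intercept_sum"], new_sums["intercept_sum"]
                if new_g == 0.0:
                    cost = 0.0 if old_g == 0.0 else -np.inf
                else:
                    cost = (new_g - old_g) / new_g
                expo = np.clip(-cost / max(temperature, 1e-300), -700, 700)
                energy = math.exp(expo)
                accepted = rng.uniform() < energy
            if accepted:
                assign, sums = new_assign, new_sums
        temperature *= alpha
        trace_rows.append(
            {"iteration": k, **sums, "temperature": temperature, "accepted": accepted}
        )

    assignment = SplitAssignment(
        item_to_group=best_assign,
        unit_to_group=_unit_map(items, best_assign),
        n_groups=n_groups,
        level=level,
        blocks_respected=block_column is not None,
    )
    return assignment, pd.DataFrame(trace_rows)


def _balanced_partitions(items: list, n_groups: int):
    """Yield balanced labeled partitions up to permutation of equal-size groups."""
    n = len(items)
    base, extra = divmod(n, n_groups)
    caps = [base + 1 if g < extra else base for g in range(n_groups)]
    groups: list[list] = [[] for _ in range(n_groups)]

    def rec(i):
        if i == n:
            yield [list(g) for g in groups]
            return
        for g in range(n_groups):
            if len(groups[g]) >= caps[g]:
                continue
            # symmetry break: among equal-capacity groups, fill left to right
            if g > 0 and caps[g] == caps[g - 1] and not groups[g - 1]:
                continue
            groups[g].append(items[i])
            yield from rec(i + 1)
            groups[g].pop()

    yield from rec(0)


def count_balanced_partitions(n_items: int, n_groups: int) -> int:
    base, extra = divmod(n_items, n_groups)
    sizes = [base + 1] * extra + [base] * (n_groups - extra)
    total = math.factorial(n_items)
    for s in sizes:
        total //= math.factorial(s)
    from collections import Counter

    for size, mult in Counter(sizes).items():
        total //= math.factorial(mult)
    return total


def brute_force_split(
    ds: LongitudinalDataset,
    n_groups: int = 2,
    level: str = "unit",
    max_partitions: int = 100_000,
) -> tuple[SplitAssignment, dict]:
    """Exhaustive balanced-partition search (testing oracle for small cohorts).

    Returns the assignment minimizing the lexicographic (intercept sum,
    slope sum) objective, plus that assignment's four metric sums.
    """
    dss = shift_times(ds)
    items = _items_table(dss, level, None)
    n_parts = count_balanced_partitions(len(items), n_groups)
    if n_parts > max_partitions:
        raise ValueError(f"{n_parts} balanced partitions exceed the limit {max_partitions}")
    labels = _group_labels(n_groups)
    item_ids = items["item"].tolist()
    best = None
    for part in _balanced_partitions(item_ids, n_groups):
        assign = {it: labels[g] for g, grp in enumerate(part) for it in grp}
        try:
            sums = pairwise_metric_sums(group_metrics(dss, _unit_map(items, assign)))
        except DataError:
            continue
        key = _objective(sums)
        if best is None or key < best[0]:
            best = (key, assign, sums)
    if best is None:
        raise DataError("no feasible balanced partition")
    _, assign, sums = best
    return (
        SplitAssignment(
            item_to_group=assign,
            unit_to_group=_unit_map(items, assign),
            n_groups=n_groups,
            level=level,
        ),
        sums,
    )


def exclusion_report(
    ds: LongitudinalDataset, variability_threshold: float = 3.0
) -> pd.DataFrame:
    """Advisory pre-randomization exclusion flags (nothing is removed).

    Per-unit OLS slopes are computed; a unit is flagged when its slope sits
    more than ``variability_threshold`` robust SDs (1.4826 x MAD) from the
    cohort median slope — the signature of a flat, non-engrafted trajectory
    inside a growing cohort.  A parent is flagged when the coefficient of
    variation of its units' slopes exceeds the threshold.  Returns a table
    with columns ``level, id, reason, statistic``.
    """
    slopes = {}
    for unit, sub in ds.df.groupby("unit_id"):
        if sub["time"].nunique() < 2:
            continue
        slope, *_ = _pooled_ols(sub["time"].to_numpy(), sub["value"].to_numpy())
        slopes[unit] = slope
    rows = []
    vals = np.array(list(slopes.values()))
    if vals.size >= 3:
        med = np.median(vals)
        mad = 1.4826 * np.median(np.abs(vals - med))
        if mad > 0:
            for unit, s in slopes.items():
                z = (s - med) / mad
                if abs(z) > variability_threshold:
                    rows.append(
                        {"level": "unit", "id": unit, "reason": "deviant slope",
                         "statistic": float(z)}
                    )
    tab = ds.unit_table()
    for parent, sub in tab[tab["parent_id"] != ""].groupby("parent_id"):
        ss = np.array([slopes[u] for u in sub["unit_id"] if u in slopes])
        if ss.size >= 2 and abs(ss.mean()) > 0:
            cv = ss.std(ddof=1) / abs(ss.mean())
            if cv > variability_threshold:
                rows.append(
                    {"level": "parent", "id": parent,
                     "reason": "high slope variability", "statistic": float(cv)}
                )
    return pd.DataFrame(rows, columns=["level", "id", "reason", "statistic"])


class AnnealedGroupSplitter(BaseEstimator):
    """Pretreatment randomizer (scikit-learn style wrapper over sa_split).

    Attributes after fit: ``assignment_`` (SplitAssignment), ``trace_``
    (per-iteration DataFrame), ``metric_sums_`` (four sums of the returned
    assignment).
    """

    def __init__(
        self,
        n_groups: int = 2,
        n_iterations: int = 100,
        alpha: float = 0.5,
        temperature0: float = 1.0,
        seed: int = 0,
        block_column=None,
        level: str = "unit",
    ):
        self.n_groups = n_groups
        self.n_iterations = n_iterations
        self.alpha = alpha
        self.temperature0 = temperature0
        self.seed = seed
        self.block_column = block_column
        self.level = level

    def fit(self, ds: LongitudinalDataset, y=None):
        self.assignment_, self.trace_ = sa_split(
            ds,
            n_groups=self.n_groups,
            n_iterations=self.n_iterations,
            alpha=self.alpha,
            temperature0=self.temperature0,
            seed=self.seed,
            block_column=self.block_column,
            level=self.level,
        )
        dss = shift_times(ds)
        self.metric_sums_ = pairwise_metric_sums(
            group_metrics(dss, self.assignment_.unit_to_group)
        )
        return self

    def predict(self, unit_ids) -> list:
        """Group label for each unit id."""
        return [self.assignment_.unit_to_group[u] for u in unit_ids]
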