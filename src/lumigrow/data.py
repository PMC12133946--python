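"""Long-format longitudinal measurement data: container, CSV I/O, transforms.

The central object is :class:`LongitudinalDataset`, a thin validated wrapper
around a tidy :class:`pandas.DataFrame` with one row per (experimental unit,
timepoint).  Units (e.g. injected mammary glands) may nest in parents (mice)
and blocks (cages); every unit carries exactly one condition label.
Measurements are strictly positive raw readouts (e.g. bioluminescence total
flux in photons/second) or their log-transformed values.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "LongitudinalDataset",
    "LoadReport",
    "load_long_csv",
    "write_long_csv",
    "log_transform",
    "summarize_by_group",
    "flag_outliers",
]

REQUIRED_COLUMNS = ("unit_id", "condition", "time", "value")
OPTIONAL_COLUMNS = ("parent_id", "block")


class DataError(ValueError):
    """Raised when input data violate the dataset invariants."""


@dataclass(frozen=True)
class LoadReport:
    """Bookkeeping from a CSV load: how many rows were dropped and why."""

    n_rows_read: int = 0
    n_dropped_missing_value: int = 0


@dataclass
class LongitudinalDataset:
    """Validated long-format repeated measurements.

    Parameters
    ----------
    df : pandas.DataFrame
        Columns ``unit_id, condition, time, value`` and optionally
        ``parent_id, block``.  One row per (unit, time); missing timepoints
        are simply absent rows, never sentinels.
    value_name, time_name : str
        Human-readable labels carried through to outputs.
    log_base : int or None
        ``10``, ``2`` or ``None``; records whether ``value`` is already on a
        log scale.  Raw (``None``) values must be strictly positive.
    """

    df: pd.DataFrame
    value_name: str = "value"
    time_name: str = "time"
    log_base: int | None = None
    load_report: LoadReport = field(default_factory=LoadReport)

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True).copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise DataError(f"missing required columns: {missing}")
        for col in OPTIONAL_COLUMNS:
            if col not in df.columns:
                df[col] = ""
        df["unit_id"] = df["unit_id"].astype(str)
        df["condition"] = df["condition"].astype(str)
        df["parent_id"] = df["parent_id"].fillna("").astype(str)
        df["block"] = df["block"].fillna("").astype(str)
        df["time"] = pd.to_numeric(df["time"])
        df["value"] = pd.to_numeric(df["value"])
        if df["value"].isna().any() or df["time"].isna().any():
            raise DataError("NaN time or value rows must be dropped before construction")

        dup = df.duplicated(subset=["unit_id", "time"], keep=False)
        if dup.any():
            pair = df.loc[dup, ["unit_id", "time"]].iloc[0]
            raise DataError(
                f"duplicate (unit_id, time) pair: ({pair['unit_id']!r}, {pair['time']})"
            )
        for col in ("condition", "parent_id", "block"):
            per_unit = df.groupby("unit_id")[col].nunique()
            bad = per_unit[per_unit > 1]
            if len(bad):
                raise DataError(
                    f"unit(s) {list(bad.index)} map to more than one {col}"
                )
        if self.log_base is None and (df["value"] <= 0).any():
            rows = df.index[df["value"] <= 0].tolist()
            raise DataError(f"non-positive raw values at rows {rows}")
        self.df = df[list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS)]

    # -- convenience accessors -------------------------------------------------
    @property
    def units(self) -> list[str]:
        return sorted(self.df["unit_id"].unique())

    @property
    def conditions(self) -> list[str]:
        return sorted(self.df["condition"].unique())

    @property
    def n_records(self) -> int:
        return len(self.df)

    def unit_table(self) -> pd.DataFrame:
        """One row per unit with its condition/parent/block labels."""
        return (
            self.df.groupby("unit_id")[["condition", "parent_id", "block"]]
            .first()
            .reset_index()
        )

    def subset_conditions(self, conditions) -> "LongitudinalDataset":
        keep = self.df["condition"].isin(list(conditions))
        return dataclasses.replace(self, df=self.df[keep], load_report=LoadReport())

    def replace_values(self, values: np.ndarray, log_base=None) -> "LongitudinalDataset":
        df = self.df.copy()
        df["value"] = np.asarray(values, dtype=float)
        return dataclasses.replace(self, df=df, log_base=log_base, load_report=LoadReport())


def load_long_csv(
    path,
    schema: dict | None = None,
    value_name: str = "value",
    time_name: str = "time",
) -> LongitudinalDataset:
    """Read a long-format CSV into a :class:`LongitudinalDataset`.

    ``schema`` maps canonical column names (``unit_id``, ``condition``,
    ``time``, ``value``, optionally ``parent_id``, ``block``) to the column
    names actually present in the file.  Rows with an empty value cell are
    dropped and counted in the load report.
    """
    schema = dict(schema or {})
    raw = pd.read_csv(path)
    rename = {}
    for canon in REQUIRED_COLUMNS + OPTIONAL_COLUMNS:
        src = schema.get(canon, canon)
        if src in raw.columns:
            rename[src] = canon
        elif canon in REQUIRED_COLUMNS:
            raise DataError(f"column {src!r} (for {canon!r}) not found in {path}")
    df = raw.rename(columns=rename)
    n_read = len(df)
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    dropped = int(df["value"].isna().sum())
    df = df[df["value"].notna()]
    report = LoadReport(n_rows_read=n_read, n_dropped_missing_value=dropped)
    return LongitudinalDataset(
        df=df, value_name=value_name, time_name=time_name, load_report=report
    )


def write_long_csv(ds: LongitudinalDataset, path) -> None:
    """Write the dataset back to CSV (canonical column names)."""
    ds.df.to_csv(path, index=False)


def log_transform(ds: LongitudinalDataset, base: int = 10) -> LongitudinalDataset:
    """Replace values by log_base(value); refuses a second transform."""
    if base not in (10, 2):
        raise DataError(f"log base must be 10 or 2, got {base}")
    if ds.log_base is not None:
        raise DataError(f"dataset already log{ds.log_base}-transformed")
    vals = ds.df["value"].to_numpy(dtype=float)
    bad = np.nonzero(vals <= 0)[0]
    if bad.size:
        raise DataError(f"non-positive values at rows {bad.tolist()}; cannot log-transform")
    out = np.log(vals) / math.log(base)
    return ds.replace_values(out, log_base=base)


def summarize_by_group(ds: LongitudinalDataset) -> pd.DataFrame:
    """Per-(condition, time) mean and standard error on the analysis scale.

    Returns columns ``condition, time, n, mean, se``; ``se`` is the sample
    standard deviation over sqrt(n) and is NaN when n = 1.
    """
    if ds.n_records == 0:
        raise DataError("empty dataset")
    g = ds.df.groupby(["condition", "time"])["value"]
    out = g.agg(n="size", mean="mean", sd=lambda s: s.std(ddof=1)).reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out.drop(columns="sd").sort_values(["condition", "time"]).reset_index(drop=True)


def flag_outliers(
    ds: LongitudinalDataset, z_threshold: float = 4.0
) -> tuple[pd.DataFrame, list[str]]:
    """Advisory outlier flags from per-unit robust residual z-scores.

    For each unit with at least 3 records, an ordinary least-squares line of
    value on time is fitted; residuals are standardized by 1.4826 times the
    unit's median absolute deviation.  Records with |robust z| above the
    threshold are flagged (nothing is ever removed).  Returns the flag table
    (``unit_id, time, robust_z``) and the list of units skipped for having
    fewer than 3 records.
    """
    if z_threshold <= 0:
        raise DataError("z_threshold must be positive")
    flags = []
    skipped: list[str] = []
    for unit, sub in ds.df.groupby("unit_id"):
        if len(sub) < 3:
            skipped.append(str(unit))
            continue
        X = sm.add_constant(sub["time"].to_numpy(dtype=float))
        resid = sm.OLS(sub["value"].to_numpy(dtype=float), X).fit().resid
        mad = np.median(np.abs(resid - np.median(resid)))
        scale = 1.4826 * mad
        if scale == 0:
            # perfectly collinear residuals: nothing to flag
            continue
        z = resid / scale
        for t, zi in zip(sub["time"], z):
            if abs(zi) > z_threshold:
                flags.append({"unit_id": unit, "time": t, "robust_z": zi})
    table = pd.DataFrame(flags, columns=["unit_id", "time", "robust_z"])
    return table, skipped
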