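"""Maximum-likelihood fitting, likelihood-ratio tests, and bootstrap intervals.

The marginal model is y ~ N(X beta, sigma^2 (I + lambda Z Z^T)) with
lambda = sigma_b^2 / sigma^2.  For a fixed lambda both beta (by GLS) and
sigma^2 (in closed form) profile out, leaving a one-dimensional concave
search over log lambda; the unit-indicator structure of Z makes every
profile evaluation O(q p^2) via per-unit Woodbury identities.  ML (not REML)
is used throughout so nested fits with different fixed effects remain
likelihood-comparable.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .data import LongitudinalDataset
from .design import DesignMatrices, ModelSpec, build_design

__all__ = [
    "MLFit",
    "LRTResult",
    "MixedLMGrowthModel",
    "fit_ml",
    "lrt",
    "pairwise_lrt_table",
    "bootstrap_ci",
    "drop_interaction_columns",
]

_LOGLAM_LO, _LOGLAM_HI = -18.0, 12.0


@dataclass
class MLFit:
    """Maximum-likelihood fit of the random-intercept growth model."""

    beta: pd.Series  # labeled fixed effects (includes the intercept)
    sigma2: float
    sigma_b2: float
    loglik: float
    n_params: int
    converged: bool
    boundary: bool  # sigma_b^2 pinned at (numerically) zero


@dataclass
class LRTResult:
    """Likelihood-ratio test of nested fits referred to chi-squared."""

    statistic: float
    df: int
    p_value: float


def _profile_pieces(design: DesignMatrices):
    """Sufficient statistics for O(1)-per-unit profile likelihood evaluation."""
    X, Z, y = design.X, design.Z, design.y
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    n_j = Z.sum(axis=0)  # obs per unit
    Sx = Z.T @ X  # per-unit covariate sums (q x p)
    Sy = Z.T @ y  # per-unit response sums
    return XtX, Xty, yty, n_j, Sx, Sy


def _profile_loglik(loglam: float, pieces, n: int):
    """Profile log-likelihood over beta and sigma^2 at fixed log lambda."""
    XtX, Xty, yty, n_j, Sx, Sy = pieces
    lam = np.exp(loglam)
    w = lam / (1.0 + lam * n_j)  # per-unit Woodbury weight
    A = XtX - (Sx.T * w) @ Sx
    c = Xty - Sx.T @ (w * Sy)
    beta = np.linalg.solve(A, c)
    # r' V0^{-1} r via the same per-unit Woodbury correction on the raw pieces
    rss = yty - 2 * Xty @ beta + beta @ (XtX @ beta)
    unit_res = Sy - Sx @ beta
    quad = rss - float((w * unit_res) @ unit_res)
    sigma2 = quad / n
    logdet = float(np.sum(np.log1p(lam * n_j)))
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) - 0.5 * logdet
    return ll, beta, sigma2


def fit_ml(design: DesignMatrices, use_random_intercepts: bool = True) -> MLFit:
    """Fit the random-intercept model by profiled maximum likelihood.

    Profiles beta and sigma^2 analytically and optimizes log lambda
    (lambda = sigma_b^2/sigma^2) numerically from several deterministic
    starting brackets; the lambda -> 0 boundary (no unit-level variance) is
    evaluated explicitly and kept if it wins.
    """
    n, p = design.X.shape
    if n <= p + 2:
        raise ValueError(f"need n_obs > p + 2 (n={n}, p={p})")
    pieces = _profile_pieces(design)

    if not use_random_intercepts or design.Z.shape[1] == 0:
        ll0, beta0, s20 = _profile_loglik(_LOGLAM_LO, pieces, n)
        return MLFit(
            beta=pd.Series(beta0, index=design.labels),
            sigma2=float(s20), sigma_b2=0.0, loglik=float(ll0),
            n_params=p + 1, converged=True, boundary=False,
        )

    def neg(loglam):
        return -_profile_loglik(float(loglam), pieces, n)[0]

    best = None
    converged = True
    # deterministic restarts across the plausible lambda range
    for lo, hi in [(_LOGLAM_LO, 0.0), (-6.0, 6.0), (0.0, _LOGLAM_HI)]:
        res = optimize.minimize_scalar(
            neg, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10}
        )
        if not res.success:
            converged = False
        if best is None or res.fun < best.fun:
            best = res
    # explicit boundary check: sigma_b^2 = 0
    ll_bound = -neg(_LOGLAM_LO)
    if ll_bound >= -best.fun - 1e-10:
        loglam, boundary = _LOGLAM_LO, True
    else:
        loglam, boundary = float(best.x), best.x < _LOGLAM_LO + 1.0
    ll, beta, sigma2 = _profile_loglik(loglam, pieces, n)
    lam = np.exp(loglam)
    sigma_b2 = 0.0 if boundary else float(lam * sigma2)
    return MLFit(
        beta=pd.Series(beta, index=design.labels),
        sigma2=float(sigma2),
        sigma_b2=sigma_b2,
        loglik=float(ll),
        n_params=p + 2,
        converged=converged,
        boundary=boundary,
    )


def lrt(full: MLFit, restricted: MLFit, tol: float = 1e-6) -> LRTResult:
    """Likelihood-ratio test of a restricted fit nested in a full fit."""
    if not (full.converged and restricted.converged):
        raise ValueError("refusing LRT on a non-converged fit")
    df = full.n_params - restricted.n_params
    if df < 0:
        raise ValueError("restricted model must not have more parameters than the full model")
    stat = 2.0 * (full.loglik - restricted.loglik)
    if stat < -tol * max(1.0, abs(full.loglik)):
        raise ValueError(
            f"restricted log-likelihood exceeds the full one ({stat=:.3g}); optimizer failure"
        )
    stat = max(stat, 0.0)
    if df == 0:
        # identical models: nothing tested, no evidence against the null
        return LRTResult(statistic=stat, df=0, p_value=1.0)
    return LRTResult(statistic=stat, df=df, p_value=float(stats.chi2.sf(stat, df)))


def drop_interaction_columns(design: DesignMatrices) -> DesignMatrices:
    """Copy of the design with all time-basis x condition columns removed."""
    keep = [
        (lab, j) for lab, j in design.column_map.items() if ":cond[" not in lab
    ]
    labels = [lab for lab, _ in keep]
    idx = [j for _, j in keep]
    return dataclasses.replace(
        design,
        X=design.X[:, idx],
        column_map={lab: i for i, lab in enumerate(labels)},
    )


def pairwise_lrt_table(
    ds: LongitudinalDataset, spec: ModelSpec | None = None
) -> pd.DataFrame:
    """Pairwise growth-rate LRTs, one row per condition pair.

    For each pair the full (with time x condition interaction) and restricted
    (without) models are fit on the subset of the data containing only those
    two conditions; columns are ``Comparison, p_value, statistic``.
    """
    spec = spec or ModelSpec()
    rows = []
    for a, b in itertools.combinations(ds.conditions, 2):
        sub = ds.subset_conditions([a, b])
        sub_spec = ModelSpec(
            spline_knots=spec.spline_knots,
            reference=a if spec.reference not in (a, b) else spec.reference,
            grouping=spec.grouping,
        )
        full_design = build_design(sub, sub_spec)
        full = fit_ml(full_design)
        restricted = fit_ml(drop_interaction_columns(full_design))
        res = lrt(full, restricted)
        rows.append(
            {"Comparison": f"{a} vs. {b}", "p_value": res.p_value, "statistic": res.statistic}
        )
    return pd.DataFrame(rows)


def bootstrap_ci(
    ds: LongitudinalDataset,
    statistic,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    max_failure_rate: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap interval by unit-level case resampling.

    Whole unit trajectories are resampled with replacement within each
    condition (preserving group sizes and the repeated-measures dependence);
    ``statistic`` maps a LongitudinalDataset to a scalar.
    """
    if B < 200:
        raise ValueError("B must be at least 200")
    rng = np.random.default_rng(seed)
    unit_tab = ds.unit_table()
    by_cond = {c: g["unit_id"].tolist() for c, g in unit_tab.groupby("condition")}
    frames = {u: g for u, g in ds.df.groupby("unit_id")}
    vals = []
    failures = 0
    for _ in range(B):
        parts = []
        for cond, units in by_cond.items():
            chosen = rng.choice(units, size=len(units), replace=True)
            for rep, u in enumerate(chosen):
                f = frames[u].copy()
                f["unit_id"] = f"{u}~{rep}"  # keep (unit, time) uniqueness
                parts.append(f)
        boot = dataclasses.replace(
            ds, df=pd.concat(parts, ignore_index=True), load_report=ds.load_report.__class__()
        )
        try:
            vals.append(float(statistic(boot)))
        except Exception:
            failures += 1
    if failures > max_failure_rate * B:
        raise RuntimeError(f"statistic failed on {failures}/{B} bootstrap resamples")
    lo = (1.0 - level) / 2.0
    return tuple(np.quantile(vals, [lo, 1.0 - lo]))


class MixedLMGrowthModel(BaseEstimator):
    """Frequentist random-intercept growth model (scikit-learn style).

    Maximum-likelihood fit of ``value ~ time_basis * condition + (1 | unit)``
    by the profiled marginal likelihood.

    Attributes
    ----------
    design_ : DesignMatrices
    fit_ : MLFit
    beta_ : pandas.Series
    sigma2_, sigma_b2_, loglik_ : float
    """

    def __init__(self, knots=(), reference=None, use_random_intercepts: bool = True):
        self.knots = knots
        self.reference = reference
        self.use_random_intercepts = use_random_intercepts

    def fit(self, ds: LongitudinalDataset, y=None):
        spec = ModelSpec(spline_knots=tuple(self.knots), reference=self.reference)
        self.design_ = build_design(ds, spec)
        self.fit_ = fit_ml(self.design_, use_random_intercepts=self.use_random_intercepts)
        self.beta_ = self.fit_.beta
        self.sigma2_ = self.fit_.sigma2
        self.sigma_b2_ = self.fit_.sigma_b2
        self.loglik_ = self.fit_.loglik
        self.converged_ = self.fit_.converged
        return self

    def predict(self, conditions, times) -> np.ndarray:
        """Population-level fitted growth curve, (n_conditions, n_times)."""
        Xn = self.design_.population_matrix(list(conditions), list(times))
        return (Xn @ self.beta_.to_numpy()).reshape(len(list(conditions)), -1)

    def lrt_interaction(self) -> LRTResult:
        """LRT of the time x condition interaction against the nested fit."""
        restricted = fit_ml(
            drop_interaction_columns(self.design_),
            use_random_intercepts=self.use_random_intercepts,
        )
        return lrt(self.fit_, restricted)
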