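# Methods

## Data model

`LongitudinalDataset` holds long-format repeated measurements: one row per
(unit, time) with a condition label and optional parent (animal) and block
(cage) labels. Units map to exactly one condition/parent/block; missing
timepoints are absent rows, never sentinels, so every model conditions on
the observed rows only — valid under missingness at random, which is the
working assumption throughout. Analysis happens on a log scale (log10 for
in vivo flux, log2 for screen confluence/fluorescence); the caller chooses
the base explicitly and a second transform is refused. Rows with empty
value cells are dropped at load and counted in the load report.

Outlier flagging is advisory only: per unit, residuals from that unit's OLS
line against time are standardized by 1.4826 × MAD, and records beyond a
z-threshold (default 4) are reported but never removed. The default is
deliberately lax — it should only catch gross, tracer-failure-like drops;
subtler anomalies are a judgment call for the analyst, not the software.

## Design matrices and priors

`build_design` renders `value ~ time_basis * condition + (1 | unit)` with
reference-level dummy coding (reference = alphabetically first condition
unless set; set it explicitly when a CTRL/DMSO label exists). The time
basis is either plain time or a truncated-power linear spline
`[t, (t−k₁)₊, …]` — the simplest basis consistent with piecewise-linear
kinetics such as a screen whose slope breaks at 25 h. With a full
interaction, the fixed-effect count is (1 + n_basis) × n_conditions.

Default priors are the weakly-informative autoscaling family:
`β_k ~ N(0, 2.5·s_y/s_{x_k})`, `α ~ N(m_y, 2.5·s_y)` with covariates
mean-centered when forming the intercept prior (the reported intercept is
back-transformed to the uncentered parameterization), and
`σ ~ Exponential(1/s_y)`. The hyperprior on the random-intercept scale σ_b
is not pinned down by the autoscaling convention; we adopt
`σ_b ~ Exponential(1/s_y)`, the same family as σ, for symmetry and
simplicity. This is a declared design choice, exposed as a knob
(`PriorSpec.sigma_b_rate`), not an inference from any reference system.
Informative intercept priors (e.g. `N(7, 2)` for log10 flux where 7 is a
typical treatment-start threshold) can be passed verbatim.

## Posterior sampling

The model is conditionally conjugate given the two scales, so the sampler
is blocked Gibbs:

1. (α, β, b) | σ, σ_b — one joint draw from the exact multivariate-normal
   conditional (a single Cholesky factorization of the posterior precision
   per iteration);
2. σ | rest and σ_b | b — univariate slice sampling (stepping-out, width 1)
   on the log scale, since the exponential priors break conjugacy for the
   scales; both conditionals are smooth and unimodal.

Defaults: 4 chains × 2000 iterations, first half discarded as warmup, all
chain seeds spawned from one user seed (identical inputs + seed give
byte-identical draws). Initialization is deterministic: α at mean(y), β and
b at 0, σ at sd(y). Convergence is summarized per parameter by
rank-normalized split-R̂ and bulk ESS (via arviz) with pass thresholds
R̂ < 1.01 and ESS > 400 — stricter than the minimal conventions, because
these model sizes make extra iterations cheap. Constant columns have
undefined R̂ and are excluded from the pass decision. A `prior_only` mode
draws from the priors through the same code path, used to verify prior
recovery; a fixed-σ, no-random-effects mode reduces the posterior to a
closed-form conjugate normal, used as an exact oracle in the tests.

## Effect sizes

All effect operations are pure functions of the draw matrix. For
linear-time models the primary effect is the slope difference between two
conditions (time coefficient + interaction coefficient, reference
interaction ≡ 0). Posteriors are summarized as K = 100 quantile dots at
probabilities (i − 0.5)/K with linear interpolation — symmetric, standard,
and it makes "98 of 100 dots above zero = 98%" exact — plus exceedance
probabilities P(effect > t) as simple draw fractions.

For spline models, effects are predicted-difference curves over a time grid
(population level, b = 0): per-time median with nested central bands at
25/50/80/95% by default. Endpoint contrasts are the
difference-in-differences of predicted means,
`(M[t1,c1] − M[t1,c0]) − (M[t0,c1] − M[t0,c0])` — a log fold-change on
log2-scale data. Screen-wide rankings sort conditions by posterior mean
endpoint contrast vs control with 95% intervals and P(>0); the heatmap
table uses the posterior MEAN difference per (condition, time) while curves
use the median center — both choices are deliberate and documented here
because "average difference" and a robust curve center serve different
readers.

## Maximum likelihood and the LRT

The marginal model `y ~ N(Xβ, σ²(I + λZZᵀ))`, λ = σ_b²/σ², profiles β (GLS)
and σ² (closed form) at fixed λ, leaving a 1-D concave search over log λ;
the unit-indicator structure of Z reduces every profile evaluation to
per-unit Woodbury corrections (O(q·p²)). The optimizer runs bounded scalar
minimization from three deterministic brackets and explicitly evaluates the
λ → 0 boundary, keeping it when it wins (no unit-level variance). ML — not
REML — is used throughout, because REML likelihoods are not comparable
across different fixed-effect structures and the whole point is nested
fixed-effect tests.

Growth-rate tests compare the full model with the time × condition
interaction against the nested model without it: statistic
2·(ℓ_full − ℓ_restricted), df = parameter-count difference, upper-tail χ².
Pairwise comparisons refit both models on the two-condition subset of the
data. Boundary-corrected mixture-χ² references are out of scope since only
fixed effects are tested. Bootstrap intervals use unit-level case
resampling stratified by condition — whole trajectories are resampled so
the within-unit dependence and group sizes survive — with percentile
endpoints (the simplest defensible variant).

## Pretreatment randomization

Before treatment, units (or whole animals — randomization at the parent
level pools all of an animal's units) are split into balanced groups whose
pretreatment kinetics match. Times are first shifted so the global maximum
is 0, making each group's pooled-OLS intercept the average of its last
measurements. Four imbalance metrics are computed per candidate split:
the sums over group pairs of |Δslope|, |Δintercept|, |Δse_slope|,
|Δse_intercept|. Absolute differences are used because a signed pairwise
sum can be driven arbitrarily negative and is not a meaningful minimization
target.

The annealer runs 100 iterations by default. Each iteration draws a fresh
random balanced split (stratified within blocks when blocking) as the
proposal; regenerating the split each iteration, rather than perturbing the
current one by a single swap, is essential at this cooling rate — with
α = 0.5 the temperature is ~10⁻³ after 10 iterations, so an incremental
search freezes into whatever single-swap local minimum it first enters,
while fresh proposals keep exploring globally for all 100 iterations. A
proposal replaces the current split outright when BOTH the intercept and
slope sums decrease; otherwise it is accepted with probability
exp(−cost/T), cost = (Γ_new − Γ_old)/Γ_new on the intercept sum Γ, with
T_k = T₀·αᵏ (T₀ = 1, α = 0.5). Equal-Γ proposals have cost 0 and are always
accepted. The two SE metrics are traced as diagnostics but do not enter
acceptance: stable SE traces indicate the split is not trading mean balance
for variance imbalance. The returned assignment is the best split examined
anywhere in the run by lexicographic (intercept sum, slope sum) — never
worse than the initial split. `brute_force_split` enumerates all balanced
partitions (dividing out group-label symmetry) as an exact oracle for small
cohorts; on random 8-unit cohorts the annealer lands within 10% of the
exhaustive optimum in ≈93% of runs and finds it exactly in most.

The exclusion report flags, before randomization, units whose OLS slope
sits more than a threshold (default 3) robust SDs from the cohort median —
the signature of a non-engrafted, flat trajectory — and parents whose
units' slopes have a coefficient of variation above the threshold. Nothing
is removed automatically.

## Synthetic data and sensitivity

The generator emulates a two-arm xenograft cohort on the log scale: unit
intercepts `b_j ~ N(5, 1)` (log10-flux starting levels), control slope
0.05/day, a treatment × time interaction of configurable magnitude, 10
timepoints over 60 days, Gaussian noise (default sd 1), 10%
missing-at-random dropout, optional single-record outlier drops (on a
dedicated RNG substream so trajectories are unchanged when outliers are
toggled), and optional unit-in-parent nesting and arm-level baseline
offsets. These defaults are plausibility choices for scale, not estimates
of any particular dataset. What the generator does NOT emulate: non-linear
kinetics (saturation, regression), heteroscedastic or heavy-tailed noise,
informative dropout, and serial correlation beyond the shared intercept —
so passing tests certify the inferential machinery under its own
assumptions, not robustness to their violation.

The sensitivity engine maps credible-interval width of the interaction over
a lattice of noise variance (1–5) × group size (2–15) × effect magnitude
(0–0.2 step 0.05), the full grid being 350 cells per replicate. Each cell
simulates, refits the Bayesian model, and records the interaction's
posterior mean, 95% interval, width, and truth coverage; non-converged fits
are flagged and excluded from summaries. Inside the grid the sampler runs a
reduced 2 chains × 1000 iterations — a desk-scale choice that leaves
interval endpoints accurate to well under the widths being compared — while
single analyses keep the full 4 × 2000 default. The package's own checks
run a 3 × 4 × 2 sub-grid at 5 replicates per cell; widths decrease
monotonically in group size and increase in variance (Spearman |ρ| = 1.0 on
cell averages), with pooled 95%-interval coverage near nominal.

## Numerical notes and limitations

* All randomness flows from a single user seed via `SeedSequence` spawning;
  no global RNG state is touched.
* The ML optimizer tolerance is 1e-10 on log λ; LRT refuses fits flagged
  non-converged and errors if the restricted likelihood exceeds the full
  one beyond tolerance (an optimizer-failure signal). Identical models give
  statistic 0, df 0, p = 1.
* Slice-sampling divergence (overflowing scales) raises immediately rather
  than returning silent garbage.
* Only Gaussian likelihoods, random intercepts (no slopes), and nested (not
  crossed) grouping are supported; no multiplicity adjustment is applied
  across screen conditions — interpretation is via effect magnitudes and
  their uncertainty, not significance counts.
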