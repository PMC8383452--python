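# Methods

This note records the statistical procedures the package implements, the
defaults and why, and the choices made where conventions genuinely differ.

## Standardization and SIR bins

Expected counts use indirect standardization, `E_i = n_i (ΣO/Σn)`, so
`ΣE = ΣO` identically; crude SIRs `O_i/E_i` are undefined (NaN) where
`E_i = 0`.  Zero-population areas stay in the data model but are excluded
from SIR and clustering vectors — mirroring study designs that drop
unpartitionable areas rather than zero-fill them.

Verbal SIR bins partition `[0, ∞)` with a closed central bin:
`[0, 0.5)`, `[0.5, 0.9)`, `[0.9, 1.1]`, `(1.1, 1.5]`, `(1.5, 2.0]`,
`(2.0, ∞)`.  Published tables with labels like "within 10% expected" leave
the boundary convention implicit; the closed central bin matches "within",
and the convention is fixed here so bin counts are reproducible.

The annual coefficient of variation uses the sample (n−1) standard
deviation over the yearly totals; with the published five-year totals this
convention reproduces the printed 7.9% (the n-denominator gives 7.1%).

## Spatial weights

Neighbors are all areas within an inclusive 120-km centroid band
(planar Euclidean km; inputs must be pre-projected).  Moran statistics use
inverse-distance weights `w_ij = 1/d_ij`, row-standardized by default —
the convention of the common desktop tools; the unstandardized path stays
selectable for sensitivity checks.  The CAR prior reuses the same band as
binary adjacency: the neighborhood that the clustering analysis treats as
the data's correlation structure is the natural choice for the structured
random effect, and it is configurable.  Duplicate centroids are an error
(they would make `1/d` undefined); exact nearest-centre ties resolve to
the first centre with a logged warning.

## Moran's I and LISA

Global `I = (n/S0) Σ w_ij z_i z_j / Σ z_i²` with mean-centered `z`;
null expectation `−1/(n−1)`.  Pseudo p-values use uniform relabeling
permutations, one-sided toward the observed side of the expectation:
`p = (1 + #{I* at least as extreme})/(n_perm + 1)` (999 permutations by
default).  Because this directional convention gives a two-sided test
roughly twice the nominal one-tail level, "significant clustering" —
in the pipeline gate and in all calibration checks — means `p ≤ α` *and*
`I` above its expectation: the scientific alternative is positive
autocorrelation.

Local `I_i = z_i (Wz)_i / m2` with the n-denominator second moment
`m2 = Σz²/n` (conventions differ; this one keeps `Σ I_i` proportional to
global `I` under row-standardized weights).  Significance uses conditional
permutation — `z_i` held in place, the remaining values resampled among
the other areas — with per-area RNG substreams spawned from one master
seed, so results are independent of iteration order.  Significant areas
are labeled by the signs of `(z_i, (Wz)_i)`; LISA p-values are not
multiplicity-adjusted by default (an FDR option exists), matching how
published LISA counts are typically reported.

## Kulldorff scan

Circular windows grow around each centroid in distance order (distance
ties enter together), capped at 25% of the total population by default
(configurable per risk level; 50% is the hard upper bound).  Zones score
`LLR = O ln(O/E) + (T−O) ln((T−O)/(T−E))` with zero-count terms evaluated
as 0; `O > E` is a high-rate candidate, `O < E` low-rate.  Inference
conditions on the observed total: replicates redistribute `T` cases
multinomially proportional to `E`, and each reported cluster is ranked
against the replicate-wide maximum LLR *of its direction*.  Secondary
clusters are reported greedily in LLR order with no shared member area
(the strictest non-overlap rule, chosen for determinism); LLR ties break
toward smaller population, then lexicographic center id.

## BYM model and sampler

Poisson likelihood `O_i ~ Poisson(E_i θ_i)`, `log θ_i = c + βx_i + u_i +
v_i`.  The intrinsic CAR prior on `u` is the pairwise-difference form
`τ_u/2 Σ_{i~j}(u_i−u_j)²`; impropriety is handled by recentring `u` to sum
to zero (per sweep) with a flat intercept, and the prior's rank —
active areas minus connected components — enters τ_u's conjugate shape.
Isolated areas keep `u_i = 0` and are excluded from the pairwise term and
the rank.  Both precisions carry Gamma(0.5, 0.0005) hyper-priors,
read as shape–rate (the convention of the BUGS family where this
specification originates); `c` and `β` carry flat priors over the real
line.

Sampling is Metropolis-within-Gibbs, compiled with numba: random-walk
updates for each `u_i`, `v_i`, `c`, `β` and conjugate Gamma draws for the
precisions — `τ_u ~ Γ(0.5 + rank/2, 0.0005 + ½Σ_{i~j}(u_i−u_j)²)`,
`τ_v ~ Γ(0.5 + n/2, 0.0005 + ½Σv²)`.  Proposal scales adapt toward 30–45%
acceptance during burn-in only and freeze afterwards, preserving detailed
balance for retained draws; post-adaptation acceptance outside
[0.05, 0.95] is logged as a warning.  The default schedule is desk-scale —
3 chains × 30,000 iterations, burn-in 10,000, thin 10 (6,000 retained
draws) — chosen so a fit takes ~2 s and a 50-region coverage study runs in
minutes; production-scale schedules (the 10⁸-iteration tradition of BUGS
BYM analyses) are reachable through the same config.  Under this schedule
the 95% CrI for β achieves ≈ 90% empirical coverage of a generating
β = −0.07 over 50 synthetic regions (asserted ≥ 85% in the tests).

Ecological analyses are unconditional: one covariate per model run.
Covariates enter unstandardized, so the IRR `exp(β̂)` (with `β̂` the
posterior mean — this transform, not the posterior mean of `exp β`, is
what published IRR tables back out to) is "per 1 unit", e.g. per one
physician per 1000 population; a standardization flag exists but is off
by default.  The percent change in SIR per unit covariate is
`100(1 − exp β̂)`.

## Convergence diagnostics

Four checks per monitored scalar parameter (`c`, `β`, `τ_u`, `τ_v`):

- **PSRF** `R̂ = sqrt(((n−1)/n·W + B/n)/W)` over the parallel chains;
- **Geweke** Z for equality of means of the first 10% and last 50%;
- **Heidelberger–Welch**: Cramér–von Mises stationarity test on the
  standardized cusum process, discarding the head in 10% steps up to 50%,
  then a half-width test `1.96·se ≤ 0.1·|mean|`; a mean statistically
  indistinguishable from zero makes the relative criterion meaningless and
  is reported *indeterminate* rather than failed;
- **Raftery–Lewis** run-length control for the 2.5% quantile
  (±0.005 at 95%), two-state Markov method; its i.i.d. floor is ≈ 3,746
  draws, so it runs on the pooled chains (per-chain retained draws at the
  default schedule are below the pilot minimum).

Spectral variances use non-overlapping batch means with ⌊√n⌋ batches.
Fewer, longer batches (n^{1/3}-count) were considered and rejected: with
~6 degrees of freedom the Geweke score is t-distributed heavy-tailed and
flags ~10% of genuinely i.i.d. chains; √n batches restore near-nominal
calibration while still tracking autocorrelation.

Verdict per parameter: **pass** iff `R̂ ≤ 1.1`, `|Z| ≤ 1.96`, both HW
flags clear (indeterminate counts as clear) and retained draws reach the
Raftery–Lewis requirement; one failed check → **warn**, two or more →
**fail**.  The named tests come from the study's workflow; the numeric
aggregation rule is this package's own (the original relied on visual
plot inspection for burn-in).  Expect honest warn/fail verdicts on the
precision parameters at desk-scale schedules: τ_v in particular mixes
slowly under random-walk updates, which is precisely why traditional BYM
analyses used extreme run lengths.  The effect parameters' summaries are
already stable at the default schedule (coverage test above).

## Synthetic data

`generate_region` lays `n` areas (default 82) on a jittered grid, 60-km
spacing ±10 km — dense enough that the 120-km band yields a connected
graph — with log-normal populations (median 2,500 men ≥ 35, σ = 0.8,
totalling ≈ 3×10⁵ like the study's covered male population) and a
log-normal physician-density covariate (median 1 per 1,000, σ = 0.4,
optionally spatially smoothed).  `simulate_risk_surface` draws `u` from
the intrinsic CAR on the adjacency graph via the Laplacian
eigendecomposition, **scaled so `sd_u` is the geometric-mean marginal
standard deviation** (the scaled draw is exactly an iCAR draw with
precision `icar_scale/sd_u²`; an unscaled draw on this dense graph would
have marginal SD far below `sd_u`).  `simulate_cases` draws
`O_i ~ Poisson(E_i θ_i)` with `E_i = rate · n_i`, after multiplying θ
inside any planted circular clusters.

Frozen study conditions used by the tests:

| scenario | sd_u | sd_v | overall rate | emulates |
|---|---|---|---|---|
| null | 0 | 0.15 | 0.0035 | unstructured heterogeneity, per-level counts |
| clustered | 0.6 | 0.05 | 0.01 | strong structured surface, all-level totals |
| covariate | 0.3 | 0.1 | 0.0035 | β = −0.07 physician-density effect |
| metastatic-scale | 0.6 | 0.05 | 0.0012 | ~500 cases; zero-count areas occur |

The rates bracket the study's per-level five-year totals (≈ 400–3,300
cases).  A caveat the tests quantify: a CAR draw at n = 82 occasionally
carries little detectable autocorrelation under the study's weights —
even noiseless surfaces reach only ≈ 96% Moran detection — so the
clustered-scenario detection property is asserted at ≥ 90% over 40 seeds.

What the generator does **not** emulate: real Saskatchewan geography and
its very uneven area sizes, registry residence-code aggregation, age
structure within areas, or spatial confounding between covariate and risk
surface.  Passing tests therefore demonstrate the *methods* behave
correctly under the model's own assumptions, not that the published
point estimates are recoverable — those depend on the confidential
registry data.

## Numerical details and edge cases

- Permutation and MCMC seeds: every stochastic stage derives its seed
  deterministically from one master seed (SeedSequence spawning; CRC of
  stage names in the pipeline), so reruns are byte-identical.
- Pseudo p-values are never 0: `(1 + extreme)/(n_perm + 1)`.
- A constant value vector is a "zero variance" error for Moran statistics;
  a zero-total-population region is a "degenerate region" error.
- Scan zones with `E = 0` are skipped; a zone covering the whole region
  (`E = T`) is reported only as a flat-surface fallback with LLR 0.
- `log_posterior` is exposed for density cross-checks; it matches the
  generator's density by construction (round-trip test).
- The Cramér–von Mises limiting CDF uses the classical four-term
  Bessel-K series (eps 10⁻⁵).
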