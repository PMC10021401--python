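# Methods

## Model

The observation model is ecological and log-linear: for county
*i = 1..C* and year *t = 1..T*,

```
z_it = log(U5M_it / 1000) = α + Σ_k β_k x_kit + w_i + ν_i + φ_t + δ_it
```

where `x_kit` is the coverage of intervention *k* **as a proportion in
(0, 1)** and `U5M` is in deaths per 1,000 livebirths.  Working on the
proportion scale matters for interpreting coefficients: a coefficient of
6.59 for HIV prevalence means a change of one *unit proportion* (100
percentage points) multiplies mortality by e^6.59; a 1-pp change
multiplies it by e^0.0659.  Files at the I/O boundary store coverage in
percent; the conversion happens only in the readers/writers.

Random-effect structure:

* `w` — spatially structured county effect with an intrinsic-CAR (ICAR)
  prior on the county adjacency graph, constrained to sum to zero.
* `ν` — unstructured iid county effect, N(0, σ_ν1²).
* `φ` — first-order random-walk year effect, constrained to sum to zero
  for identifiability with the intercept.
* `δ` — iid space–time interaction, N(0, σ_ν2²), which **doubles as the
  residual**: the model has exactly four variance components and no
  separate observation-noise term.  This is an interpretive choice — the
  source analysis lists four components and no observation sigma — and
  the mapping (σ_w structured spatial, σ_ν1 unstructured spatial, σ_t
  temporal, σ_ν2 interaction/residual) is configurable through
  `ModelSpec` flags.

Priors: α, β_k ~ N(0, 10²); each standard deviation is half-Normal(0, 5).
These are weakly informative on the log-mortality scale (the data span
roughly z ∈ [−4.5, −0.5]); the original prior specification is not
available, and posterior summaries are insensitive to doubling either
scale in the recovery simulations.

## Sampler

All location parameters (α, β, w, ν, φ) are jointly Gaussian given the
four standard deviations, so each sweep refreshes them in **one exact
block draw**: the joint posterior precision is assembled and
Cholesky-factored (dimension 1 + K + (C−1) + C + (T−1), ≈ 118 at the
default size).  `w` and `φ` are parametrized in orthonormal sum-to-zero
bases — the proper construction of the constrained ICAR/RW1 priors, which
keeps the precision positive definite (the unconstrained joint precision
is exactly singular along the direction that shifts `w` up and `φ` down
by a constant) and makes the constraints hold to machine precision at
every retained iteration.

Each standard deviation is then updated by **slice sampling on log σ
against a collapsed conditional**: its own random-effect block is
integrated out analytically (the sufficient statistics are county-mean or
year-mean residuals, diagonal in the precomputed prior eigenbasis), after
which the block is redrawn exactly from its Gaussian conditional.
Because `w` and `ν` compete for the same county-mean residual, (σ_w, σ_ν1)
are updated jointly against the marginal with *both* fields integrated
out, and (w, ν) are redrawn from per-eigendirection 2×2 Gaussians.  This
partial collapsing removes the funnel-shaped coupling between variance
components and their fields; without it the MC-error/SD ratio of σ_ν1
sits near 8% at the test-scale chain length, versus ≈ 2% with it.  The
kernel is identical at every sweep (slice sampling needs no burn-in-only
adaptation), chains are seeded independently via `SeedSequence`, and runs
are exactly reproducible.

## Diagnostics

* **Gelman statistic** — reported as the Brooks–Gelman–Rubin *interval*
  ratio: pooled 80% interval width over the mean within-chain width,
  minus one, in percent.  The interval form is exactly 0 for identical
  chains (the variance-ratio PSRF is not, because of the (N−1)/N factor)
  and is what the original WinBUGS-era workflow plotted.  A test
  cross-checks it against arviz's split-R̂ on well-mixed chains.
* **Monte Carlo error** — batch means with batch size ⌊√N⌋ per chain;
  chain-mean variances combine as 1/M² times their sum.
* **Gate** — a parameter passes iff Gelman < 5% *and* MC-error/SD < 5%;
  the overall verdict requires all summarized parameters (intercept,
  fixed effects, variance components) to pass.  Both thresholds are
  configurable.

Significance pruning removes one factor at a time — the one whose
posterior is most centred on zero (smallest |mean|/SD) among those whose
95% credible interval contains zero — and refits until every retained
interval excludes zero or no factors remain.

## Rate arithmetic and scenarios

`ARC = 100·ln(y_end/y_start)/n` percent per year; projection is
`y0·exp(ARC/100·k)`.  The year count `n` is always the plain difference
of calendar years: 11 for 2003→2014, 8 for 2014→2022, 3 for 2022→2025.
(The source tables are internally inconsistent on this — different rows
imply different conventions — so the package fixes the unambiguous
year-difference rule and does not chase table rounding; with it the
published national U5M endpoints 69.8→59.5 give −1.45%/yr.)

Scenario rules, per factor:

* **BAU** — each county-factor continues its own 2003–2014 ARC.
* **S1** — target = best county's 2014 value (max for coverage, min for
  prevalence-type factors; ties to the lowest county id).  One national
  ARC from the national 2014 mean to the target over 8 years is applied
  to every county's own baseline.  Counties at/beyond target by 2022
  (within 1e-9 in the improvement direction) switch to the ARC reaching
  99% coverage by 2025; decreasing-good factors continue the same ARC
  (the 99% universal rule only makes sense for coverage-type indicators).
* **S2** — the fastest improving county ARC applied everywhere, all years.
* **S3** — the national-mean ARC sets national 2022/2025 targets; the
  implied period ARCs apply to each county's own baseline.
* **S4** — national 2022/2025 policy targets define the two period ARCs.

National coverage is the unweighted county mean (livebirth weights are
not available).  All trajectories are clipped to [0.001, 0.99].

Counterfactual U5M is a multiplicative adjustment of ARC-projected BAU
U5M, `exp(Σ_k β_k (x_scen − x_bau))`, rather than a full model
re-prediction: the county-year random effects are constants that cancel
in the ratio, and BAU mortality itself is projected by ARC, not by the
model.  Point predictions use posterior-mean β; `CoefficientSet`
optionally carries the full draw set for interval propagation.  Percent
change relative to BAU is the headline quantity (a relative-to-2014
variant can be derived from the same tables).  SDG attainment uses a
strict `< 25/1,000` threshold; a county exactly at 25.0 has not attained.

## Synthetic data

The generator emulates the panel the analysis assumes, with defaults
matching the fitted study conditions: 47 counties × 2003–2014; the ten
retained factors with their fitted coefficients (α = −0.9273, β from the
fitted model, HIV prevalence the one harmful factor at +6.593); variance
components σ_w = 0.5336, σ_ν1 = 0.0024, σ_t = 0.0591, σ_ν2 = 0.1398.
Coverage paths are constant-ARC exponentials — matching the projection
arithmetic — with 2003 starting levels uniform on (0.15, 0.85)
(prevalence-type factors overridden to (0.01, 0.15); county HIV
prevalence is a few percent, not tens of percent) and rates uniform on
(−5, +8) %/yr, bracketing the observed factor trends (HIV fell
≈ 4.7%/yr, facility delivery rose ≈ 4.9%/yr).  The spatial field is drawn
from the exact sum-to-zero ICAR law via the graph-Laplacian
eigendecomposition; the adjacency graph is a nearest-neighbour graph on a
jittered grid, bridged to connectivity — irregular, planar-ish contiguity
like a real county map.

What the generator does **not** emulate: survey sampling error and its
spatial smoothing in the upstream estimates, measurement error in
coverage, non-lognormal mortality noise, and any feedback between
interventions.  Passing recovery tests therefore show that the pipeline
is correct *under its own assumptions* — coefficients, variance
components, significance decisions and scenario orderings are recovered
when the world is log-linear — not that those assumptions hold in any
real panel.

## Problem sizes and numerical choices

* Recovery runs use the test-scale chains (2 × 3,000 iterations, burn-in
  1,000) on the full 47 × 12 panel — a deliberate package default that
  keeps a fit under ~10 s while leaving MC-error/SD ≈ 2%; the
  paper-scale configuration (2 × 25,000 / 5,000) is available through
  `McmcConfig` and is simply the same kernel run longer.  Smaller
  recovery simulations (pruning behaviour, σ_w ordering) use 20-county ×
  8-year panels with 2 × 1,200 / 400 chains, sizes chosen so each
  replicate is decisive while a ten-replicate experiment stays within a
  test suite's patience.
* Elastic-net penalties are on the scikit-learn scale
  (`1/(2n)‖y−Xb‖² + λ·penalty`); with that convention the lasso on a
  design with X'X = nI equals soft-thresholding at λ exactly, which the
  tests exploit.  Grid ties break toward the smaller penalty, then the
  smaller mixing weight; equal model CV-MSE breaks toward model 1 (fewer
  derived variables).  Standardization uses panel-wide mean/SD computed
  once before cross-validation.
* Cross-validation folds are grouped by county so years of one county
  never straddle the split.  A consequence worth knowing: with the
  fitted spatial variance (σ_w ≈ 0.53) the grouped-CV error is dominated
  by county effects no covariate can predict, so the minimizing penalty
  shrinks hard and true-but-small coefficients (|β| ≲ 0.05) are *not*
  reliably retained.  The selection tests therefore assert what is
  statistically attainable under these conditions — strong drivers kept,
  pure decoys dropped — rather than retention of effects
  indistinguishable from zero.
* Degenerate inputs: constant factors raise degenerate-design errors in
  the screen and the PCA index; disconnected adjacency graphs, incomplete
  panels, cyclic redundancy maps, and missing scenario-4 policy targets
  are configuration errors.  All-zero variance components are valid in
  the generator (exact log-linear surfaces used by closed-form tests).

## Known limitations

* The counterfactual transports 2003–2014 associations to 2015–2025
  unchanged; structural breaks (e.g. pandemic-era service disruption) are
  out of scope.
* Linear (in log) coverage effects: a 10-pp gain is worth the same
  multiplier at 10% baseline coverage as at 80%.
* Uncertainty in the BAU ARC projection itself is not propagated; only
  coefficient uncertainty is available for interval propagation.
* The iid interaction term absorbs residual variation; a structured
  space–time interaction (e.g. county-specific trends) is not modelled.
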