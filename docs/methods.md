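# Methods

## The asymptotic decomposition

For N groups of paired observations with means μ_{xy,i}, covariance
matrices Σ_{xy,i} and weights λ_i = n_i/Σn_j, the Pearson coefficient of
the pooled sample converges in probability to

τ_xy = (Σλ_i σ_xy,i + Σ_{i<j} λ_i λ_j Δx_ij Δy_ij) / (δ_x δ_y),
δ_x² = Σλ_i σ²_x,i + Σ_{i<j} λ_i λ_j Δx_ij²,

where Δx_ij = μ_x,i − μ_x,j. The numerator splits into a within-group
covariance term and a between-group mean-difference term; the latter
equals the weighted between-group covariance Σλ_i(μ_x,i − μ̄_x)(μ_y,i −
μ̄_y), an identity the test suite asserts to 1e−12 and the vectorized
pipeline exploits. When all group means coincide the expression reduces
to the covariance-only form Σλσ_xy/√(Σλσ²_x · Σλσ²_y).

Assumptions: within-group observations are i.i.d. (bivariate normality is
used by the simulators but not by the limit itself); groups are
independent; weights are proportional to group sizes. Degenerate inputs
(δ_x = 0 or δ_y = 0, i.e. all variances zero with identical means) raise
`UndefinedCorrelationError` rather than returning 0 or NaN — a silent
value would contaminate downstream summaries.

Three scenario families admit closed forms, used as mutual oracles with
the general expression (agreement required to 1e−10):

* **mean-shift** — groups 1, 2 at (α, 0) and (0, α), the rest at (2, 2),
  identity covariance: τ = (−λ²α² − 4λ(1−2λ)(α−2)) / (λ²α² +
  λ(1−2λ)(α−2)² + 4λ(1−2λ) + 1). Positive for α below ≈2, negative above;
  the grid extremes are ≈ −0.56 and ≈ 0.48.
* **Simpson design** — means (i, N+1−i), unit variances, common ρ:
  τ = (ρ − S/N²)/(1 + S/N²) with S = Σ_{i<j}(i−j)², driving τ toward −1
  for any ρ as N grows.
* **heteroskedastic ladder** — equal means, σ_x,i = i, σ_y = 1, common
  within-group correlation ρ: τ = ρ·σ̄/√(σ²̄), a linear attenuation whose
  slope averaged over N ∈ {10,…,100} is 0.872. (The ladder is defined by
  standard deviations σ_x,i = i, i.e. variances i²; this is the
  parameterization consistent with the 0.872 slope.)

## Sample-side estimators

`estimate_pooled_decomposition` plugs group sample moments into the same
expression: τ̂ = (s̄_xy + d_xy)/(d_x d_y). Two denominator conventions are
supported. With maximum-likelihood (n) denominators and λ_i = n_i/Σn, τ̂
is algebraically identical to the pooled Pearson r (law of total
covariance) — the package's central exact test oracle, asserted to 1e−12
on arbitrary random grouped data. The default convention is unbiased
(n−1), matching standard covariance routines; then r − τ̂ = O(1/n), and
this residual error is itself a diagnostic: across many pairs it forms a
bimodal, antisymmetric pattern tracking the classical Pearson
small-sample bias ρ(1−ρ²)/(2n), which is maximal at ρ = ±1/√3 ≈ ±0.58.

The combined ("mosaic") estimator is the size-weighted Hunter–Schmidt
average r̄ = Σλ_i r_i. The bias metric is the weighted mean squared
deviation B(ρ̂) = Σλ_i(ρ̂ − ρ̂_i)² of an across-groups estimate from the
within-group estimates. A printed variant that further divides by the
group count is available (`variant="as_printed"`), but the weighted MSD
is the default: the extra divisor would bound B by 4/N, which is
inconsistent with reported maxima, and every cross-estimator comparison
is invariant to the common factor anyway. Note that r̄ minimizes B by
construction, so B(r̄) ≤ B(ρ̂) for any other estimate is an algebraic
fact; tests assert the strict form on generated data where r̄ ≠ r*.
Groups in which a within-group correlation is undefined (a constant gene)
are excluded from r̄ and B with weight renormalization.

## Monte-Carlo studies

Scenario grids follow the published settings: n_i = 10 per group, 1000
repetitions per cell, α ∈ {−10, −9.5, …, 10}, ρ ∈ {−0.9, …, 0.9} step
0.1, N ∈ {10, 20, …, 100} (λ = 1/N ∈ [0.01, 0.1]). Each cell draws
bivariate-normal groups, pools them, and averages the pooled Pearson r
and the size-weighted within-group mean r̄ over repetitions (arithmetic
mean, no Fisher-z). The heteroskedastic attenuation slope is fitted by
unweighted OLS with intercept of cell-averaged r on ρ over all cells
pooled across N — the simplest reading of an overall linear fit; with the
N-step of 10 the analytic per-N slopes 0.886…0.868 average to 0.872.

Seeding: the root seed spawns one `SeedSequence` child per grid cell (in
grid order), so cells are independent and individually re-runnable; the
repetitions of a cell are drawn vectorized from the cell's stream. All
grids at full size run in well under a minute each on one CPU.

The estimator-MSE experiment measures E[(τ̂ − τ)²] against the per-group
sample size n_i ∈ {10, …, 100} at N = 20, with τ̂ computed from unbiased
group statistics of data drawn from the heteroskedastic family at
ρ = 0.5. That generating family is a documented stand-in — the original
experiment's exact parameters are not public — so only the decreasing
trend and the order of magnitude (≈4e−3 at n_i = 10 down to ≈4e−4 at
n_i = 100) are asserted, not exact values.

## Expression pipeline

Matrices are genes × samples on a log2-like scale (an optional log2
switch handles linear input; normalization itself is out of scope). The
annotation maps each column to (group, condition, replicate), conditions
nesting within groups. Two reductions:

* **condition means** — replicates averaged per condition;
  single-replicate conditions pass through. In the emulated compendium
  layout this takes 522 replicate columns to 254 condition means.
* **residualization** — per group, a least-squares fit of each gene on
  the condition-indicator design, keeping residuals; numerically
  identical (1e−9) to subtracting each condition's replicate mean.
  Single-replicate conditions are dropped and logged (522 → 520 columns
  in the default layout). Residual group means are zero, so on residuals
  the mean-difference term vanishes and the pooled coefficient isolates
  pure covariance heterogeneity.

The full analysis draws a uniform gene subset (default 500), enumerates
all pairs lazily, and reports per pair: r on condition means, the τ̂
decomposition with percent contributions s̄_xy/(r d_x d_y) and
d_xy/(r d_x d_y) (relative to the observed r when available, else to τ̂,
in which case they sum to exactly 1), r̄, the residual-branch r* and r̄*,
and the four bias values, plus five-number bias summaries, the
sign-agreement rate between r and d_xy among |r| ≥ 0.7 pairs, and the
residual-error profile. Each branch weights groups by its own column
counts (condition counts vs residual-column counts). Genes constant
across condition means are excluded with a logged count; an undefined
residual correlation is reported as NaN (or the branch skipped entirely
when no condition has two replicates), never as 0. Histograms in the
summary use Freedman–Diaconis bins; tables, not figures, are the
pipeline's contract.

## Synthetic generator

The generator emulates the structure of a 19-group abiotic-stress
compendium: nine stresses × {root, shoot} plus one light/seedlings
group. Without a design seed the layout mirrors the real compendium's
counts exactly (12–18 conditions per group, two replicates per condition
except three in the seedlings group, two singleton conditions → 254
condition means, 522 replicate columns, 520 residual columns); with a
seed, counts are drawn from the same ranges with exactly two singletons.

Values are multivariate normal within each group; the condition layout
only controls replication (data are homogeneous within groups — no
condition effects — mirroring the analysis's own within-group
homogeneity stance). Covariances come either from explicit 2×2 matrices
(two-gene models) or from a per-group factor model L_i L_iᵀ + diag(s²),
PSD by construction: loadings N(0, 0.6²), idiosyncratic SDs log-uniform
on [0.3, 1.0]. Between-group mean offsets have marginal SD
`mean_shift_scale` with a shared rank-one component (per-group score ×
per-gene loading, plus 30% independent jitter): compendium-wide shifts
move many genes together, which is what creates strong mean-driven
pooled correlations; fully independent offsets would make them
vanishingly rare. `mean_shift_scale = 0` yields a heteroskedasticity-only
model with identical group means.

All parameter and noise streams are keyed per group and per
(group, gene), so enlarging the gene set never perturbs existing
columns. `GroundTruth` exposes the implied per-pair group parameters and
asymptotic τ at replicate level and at condition-mean level, where each
group's covariance shrinks by its mean reciprocal replicate count —
exactly the average covariance of that group's condition-mean columns.

What passing tests show — and do not show. The generator reproduces the
compendium's group/condition/replicate structure and the statistical
mechanisms (mean heterogeneity, covariance heterogeneity), not real
microarray noise (probe effects, summarization artifacts, outliers,
missingness) or the particular magnitudes of any real data set; numeric
real-data summaries are therefore outside the test surface, while
structural claims (sign determination by d_xy, bias dominance of the
combined estimator, residual identities, consistency rates) are asserted
directly.

## Numerical choices and limitations

* Validity checks (Cauchy–Schwarz, weight positivity) at 1e−9 relative;
  closed-form equivalences at 1e−10; exact identities at 1e−12; residual
  identities at 1e−9.
* Pair enumeration is lazy (generators), so the 22,810-gene pair count
  (>260 million) is never materialized; the per-pair report buffer is
  the only O(pairs) structure, and it exists only for the analyzed
  subset.
* Test and default problem sizes (repetition counts, gene-subset sizes,
  reduced grids in unit tests) are chosen so the whole suite runs in a
  few minutes on one CPU while keeping Monte-Carlo standard errors an
  order of magnitude below the asserted tolerances.
* Not covered by design: Fisher-z pooling, confidence intervals or
  significance tests for correlations, random-effects meta-analysis,
  non-normal generators, CEL import/normalization, GO enrichment and
  network construction.
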