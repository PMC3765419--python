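# poolcorr

Diagnostics for Pearson correlation coefficients computed from a **pool of
heterogeneous data groups** — the standard situation in gene co-expression
analysis, where expression columns from many experiments (different
stresses, tissues, labs) are concatenated into one "large expression
matrix" and correlated gene by gene.

## The problem and the model

Pooling is not innocent. If observations of a gene pair (x, y) come from N
groups with group means μ_{xy,i}, covariances Σ_{xy,i} and weights
λ_i = n_i / Σn_j, the pooled Pearson coefficient converges (as group sizes
grow) not to any within-group correlation but to

    τ_xy = [ Σ_i λ_i σ_xy,i  +  Σ_{i<j} λ_i λ_j (μ_x,i − μ_x,j)(μ_y,i − μ_y,j) ] / (δ_x δ_y)

    δ_x² = Σ_i λ_i σ²_x,i + Σ_{i<j} λ_i λ_j (μ_x,i − μ_x,j)²     (δ_y² analogous)

a mixture of a **within-group covariance term** and a **between-group
mean-difference term**. The second term can dominate — a pool can show
|r| ≈ 1 for genes that are uncorrelated inside every group (ecological
fallacy), or flip the sign of a correlation that is positive inside every
group (Simpson's paradox). With equal means, heteroskedasticity across
groups attenuates the pooled coefficient toward zero.

`poolcorr` provides:

* the asymptotic decomposition above and its closed forms for three
  canonical scenario families (mean-shift, Simpson anti-diagonal design,
  heteroskedastic variance ladder);
* the plug-in estimate τ̂_xy = (s̄_xy + d_xy)/(d_x d_y) from group-level
  sample statistics, which diagnoses what drives each pooled coefficient;
* the Hunter–Schmidt combined estimator r̄ = Σλ_i r_i, the weighted
  mean-squared-deviation bias metric B(ρ̂) = Σλ_i(ρ̂ − ρ̂_i)², and the
  small-sample Pearson bias ρ(1−ρ²)/(2n);
* seeded Monte-Carlo scenario grids reproducing the canonical simulation
  results;
* an expression pipeline (condition-mean pooling, per-group linear-model
  residualization, full per-pair diagnostic reports) and a synthetic
  generator emulating a 19-group, 522-array stress compendium so the whole
  pipeline runs without any download.

## Worked example

Generate a synthetic compendium (19 groups, 254 conditions over 522
replicate columns, between-group mean shifts of SD 2) and run the full
diagnostic:

```bash
poolcorr generate --seed 5 --genes 12 --factors 2 --mean-shift-scale 2.0 --out demo/data
# wrote 12 genes x 522 replicate columns (19 groups, 254 conditions)

poolcorr analyze --matrix demo/data/matrix.tsv --annotation demo/data/annotation.tsv \
                 --subset-size 12 --seed 1 --out demo/out
# analyzed 66 pairs of 12 genes; r in [-0.925, 0.864]
```

`demo/out/summary.json` then contains (abridged):

```
n_strong_pairs            32        # pairs with |r| > 0.7
sign_agreement_rate       1.0       # every strong r takes the sign of d_xy
cov_pct_median_strong     0.012     # % of |r| explained by within-group covariance
mean_pct_median_strong    99.2      # % explained by mean differences
residual_error_mean_negative  -0.0082   # sign-split means of r − τ̂:
residual_error_mean_positive  +0.0083   # the bimodal small-sample-bias signature
corr_r_star_vs_rbar_star   0.936    # residual-based pooled vs combined estimator
```

Half the pairs correlate strongly across the pool, yet essentially all of
that magnitude (99.2% median) comes from between-group mean differences,
not from co-expression within any group; on residualized data (mean
effects removed) the pooled and combined estimators agree closely. The
bias five-number table (`bias_summary.tsv`) shows the same story:

```
   estimator      Min  1st Qu.   Median  3rd Qu.      Max
        B(r)    0.129    0.499    0.680    0.878    1.195
     B(rbar)    0.088    0.162    0.201    0.229    0.338
   B(r_star)    0.107    0.158    0.183    0.212    0.268
B(rbar_star)    0.107    0.155    0.179    0.209    0.261
```

the pooled coefficient on raw data, B(r), is far more biased against the
within-group correlations than any other estimator.

Simulation grids run the same way:

```bash
poolcorr simulate --scenario simpson --out demo/sim
# simpson: pooled r in [-0.9999, -0.7986]
```

— within-group correlation +0.9, pooled correlation ≈ −0.80 to −1.0:
Simpson's paradox at grid scale.

## Library use

```python
from poolcorr import GroupParams, GroupParamsSet, asymptotic_pooled_correlation

groups = GroupParamsSet([
    GroupParams(mean_x=0, mean_y=0, var_x=1, var_y=1, cov_xy=0, size=10),
    GroupParams(mean_x=2, mean_y=2, var_x=1, var_y=1, cov_xy=0, size=10),
])
dec = asymptotic_pooled_correlation(groups)
dec.tau             # 0.5  — spurious correlation from the mean shift alone
dec.mean_diff_term  # 1.0  (covariance term is 0)
```

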