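"""End-to-end diagnostic analysis of a grouped expression matrix.

For a random gene subset and all its pairs, the pipeline computes on
the condition-mean ("pooled") matrix: the pooled Pearson coefficient r,
the plug-in decomposition tau_hat with its covariance (sbar_xy) and
mean-difference (d_xy) terms and percent contributions, the
Hunter-Schmidt combined coefficient rbar; on the residual matrix (one
group-wise condition-indicator fit, singleton conditions dropped): the
pooled residual coefficient r* and its combined counterpart rbar*; and
for all four estimators the weighted mean-squared-deviation bias
against the within-group coefficients, summarized as five-number
tables.  Diagnostics include the residual-error profile r - tau_hat,
the sign-agreement rate between r and d_xy among strong pairs, and the
percent-contribution distribution restricted to |r| >= threshold.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError, InvalidParameterError
from .expression import condition_means, residualize, validate_annotation
from .groupstats import ResidualErrorProfile, residual_error_profile

log = logging.getLogger(__name__)

_QUANTILE_COLUMNS = ("Min", "1st Qu.", "Median", "3rd Qu.", "Max")


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the full analysis.

    ``subset_size`` genes are drawn uniformly without replacement with
    ``seed``; ``strong_threshold`` is the |r| cut-off (default 0.7, the
    conventional strong-coexpression cut) used for the sign-agreement
    and percent-contribution summaries.
    """

    subset_size: int = 500
    seed: int = 0
    convention: str = "unbiased"
    bias_variant: str = "weighted_msd"
    strong_threshold: float = 0.7

    def __post_init__(self) -> None:
        if self.subset_size < 2:
            raise InvalidParameterError("subset_size must be >= 2")
        if not (0.0 < self.strong_threshold < 1.0):
            raise InvalidParameterError("strong_threshold must lie in (0, 1)")
        if self.convention not in ("unbiased", "ml"):
            raise InvalidParameterError(f"unknown convention {self.convention!r}")
        if self.bias_variant not in ("weighted_msd", "as_printed"):
            raise InvalidParameterError(f"unknown bias variant {self.bias_variant!r}")


def enumerate_pairs(
    gene_ids: Sequence[str], subset_size: int, seed: int
) -> tuple[list[str], Iterator[tuple[str, str]]]:
    """Uniform random gene subset and a lazy iterator over its unordered pairs."""
    if subset_size > len(gene_ids):
        raise InvalidParameterError(
            f"subset_size {subset_size} exceeds the {len(gene_ids)} available genes"
        )
    rng = np.random.default_rng(seed)
    subset = [gene_ids[i] for i in rng.choice(len(gene_ids), size=subset_size, replace=False)]
    return subset, itertools.combinations(subset, 2)


def pair_count(n_genes: int) -> int:
    """C(n, 2) by integer arithmetic."""
    return math.comb(n_genes, 2)


@dataclass
class BranchStats:
    """Vectorized per-pair statistics of one matrix branch.

    All pair-indexed quantities are (g x g) symmetric arrays over the
    gene subset; ``d_var`` is the per-gene d^2 denominator component.
    """

    genes: list[str]
    pooled_r: np.ndarray
    sbar: np.ndarray
    d_xy: np.ndarray
    d_var: np.ndarray
    tau_hat: np.ndarray
    within_avg_r: np.ndarray
    bias_pooled: np.ndarray
    bias_within_avg: np.ndarray
    n_groups_used: int


def _branch_stats(
    values: pd.DataFrame,
    col_groups: pd.Series,
    convention: str,
    bias_variant: str,
    min_cols: int = 2,
) -> BranchStats:
    """Group-wise moments and the plug-in decomposition for every pair.

    Groups contributing fewer than ``min_cols`` columns are excluded
    with weight renormalization.  The mean-difference term uses the
    between-group covariance identity (equal to the literal pairwise
    double sum; the equality is asserted in the test suite).
    """
    X = values.to_numpy()
    g = X.shape[0]
    ddof = 1 if convention == "unbiased" else 0

    group_labels = [grp for grp in col_groups.unique()]
    kept = []
    for grp in group_labels:
        cols = np.flatnonzero((col_groups == grp).to_numpy())
        if len(cols) >= min_cols:
            kept.append((grp, cols))
        else:
            log.warning("group %r contributes %d column(s) < %d; excluded", grp, len(cols), min_cols)
    if not kept:
        raise DataError("no group contributes enough columns for this branch")
    lam = np.array([len(cols) for _, cols in kept], dtype=float)
    lam /= lam.sum()

    sbar = np.zeros((g, g))
    sx2bar = np.zeros(g)
    means = np.empty((len(kept), g))
    # within-group correlation accumulators with NaN-aware weights
    w_sum = np.zeros((g, g))
    r_sum = np.zeros((g, g))
    r2_sum = np.zeros((g, g))
    corr_list = []
    for gi, (grp, cols) in enumerate(kept):
        sub = X[:, cols]
        m = sub.mean(axis=1)
        means[gi] = m
        xc = sub - m[:, None]
        cov = (xc @ xc.T) / (len(cols) - ddof)
        sbar += lam[gi] * cov
        sx2bar += lam[gi] * np.diag(cov)
        sd = np.sqrt(np.diag(cov))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = cov / np.outer(sd, sd)
        corr_list.append(corr)
        ok = np.isfinite(corr)
        w_sum += lam[gi] * ok
        r_sum += lam[gi] * np.where(ok, corr, 0.0)
        r2_sum += lam[gi] * np.where(ok, corr**2, 0.0)

    grand = lam @ means
    centered = means - grand
    d_xy = np.einsum("i,ij,ik->jk", lam, centered, centered)
    d_var = sx2bar + np.diag(d_xy)
    with np.errstate(invalid="ignore", divide="ignore"):
        tau_hat = (sbar + d_xy) / np.sqrt(np.outer(d_var, d_var))
        within_avg = r_sum / w_sum
        pooled_r = _corr_matrix(X)
        # B(pooled) and B(within-average) against the same within-group set
        bias_pooled = (pooled_r**2 * w_sum - 2 * pooled_r * r_sum + r2_sum) / w_sum
        bias_within = (within_avg**2 * w_sum - 2 * within_avg * r_sum + r2_sum) / w_sum
    if bias_variant == "as_printed":
        bias_pooled = bias_pooled / len(kept)
        bias_within = bias_within / len(kept)
    return BranchStats(
        genes=list(values.index),
        pooled_r=pooled_r,
        sbar=sbar,
        d_xy=d_xy,
        d_var=d_var,
        tau_hat=tau_hat,
        within_avg_r=within_avg,
        bias_pooled=bias_pooled,
        bias_within_avg=bias_within,
        n_groups_used=len(kept),
    )


def _corr_matrix(X: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix with NaN (not 0) for constant rows."""
    xc = X - X.mean(axis=1, keepdims=True)
    ss = np.einsum("ij,ij->i", xc, xc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ xc.T) / np.sqrt(np.outer(ss, ss))
    r[ss == 0.0, :] = np.nan
    r[:, ss == 0.0] = np.nan
    return r


def _five_number(values: np.ndarray) -> dict[str, float]:
    v = values[np.isfinite(values)]
    if v.size == 0:
        return {c: math.nan for c in _QUANTILE_COLUMNS}
    q = np.quantile(v, [0.0, 0.25, 0.5, 0.75, 1.0])
    return dict(zip(_QUANTILE_COLUMNS, map(float, q)))


def _fd_histogram(values: np.ndarray) -> dict:
    """Freedman-Diaconis histogram of finite values, as plain lists."""
    v = values[np.isfinite(values)]
    if v.size < 2:
        return {"bin_edges": [], "counts": []}
    counts, edges = np.histogram(v, bins="fd")
    return {"bin_edges": edges.tolist(), "counts": counts.tolist()}


@dataclass
class AnalysisResult:
    """Per-pair report, bias five-number summaries and diagnostics."""

    pairs: pd.DataFrame
    bias_summary: pd.DataFrame
    summary: dict
    residual_profile: ResidualErrorProfile | None = None
    dropped_columns: pd.DataFrame | None = None
    excluded_genes: list[str] = field(default_factory=list)


def run_full_analysis(
    matrix: pd.DataFrame, annotation: pd.DataFrame, config: AnalysisConfig
) -> AnalysisResult:
    """Run the whole diagnostic pipeline on one matrix + annotation.

    The pooled branch analyses condition means with group weights from
    condition counts; the residual branch analyses replicate-level
    residuals with weights from its own column counts.  Pairs whose
    pooled correlation is undefined (a gene constant across condition
    means) are excluded with a logged count; an undefined residual
    correlation is reported as NaN, never as 0.
    """
    ann = validate_annotation(matrix, annotation)

    cm = condition_means(matrix, ann)
    rm = residualize(matrix, ann)

    # gene subset, excluding genes constant across condition means
    subset, _ = enumerate_pairs(list(matrix.index), config.subset_size, config.seed)
    cm_sub = cm.values.loc[subset]
    spread = cm_sub.to_numpy().std(axis=1)
    excluded = [gene for gene, s in zip(subset, spread) if s == 0.0]
    if excluded:
        log.warning("excluding %d constant gene(s) from the analysis", len(excluded))
        subset = [gene for gene in subset if gene not in set(excluded)]
        cm_sub = cm.values.loc[subset]
    if len(subset) < 2:
        raise DataError("fewer than 2 non-constant genes in the subset")

    pooled = _branch_stats(
        cm_sub, cm.condition_groups, config.convention, config.bias_variant
    )

    residual_branch = None
    if rm.values.shape[1] > 0:
        residual_branch = _branch_stats(
            rm.values.loc[subset], rm.sample_groups, config.convention, config.bias_variant
        )
    else:
        log.warning("no multi-replicate conditions: residual branch skipped")

    iu = np.triu_indices(len(subset), k=1)
    d_x = np.sqrt(pooled.d_var)
    r = pooled.pooled_r[iu]
    tau_hat = pooled.tau_hat[iu]
    sbar = pooled.sbar[iu]
    d_xy = pooled.d_xy[iu]
    dxdy = np.outer(d_x, d_x)[iu]
    with np.errstate(invalid="ignore", divide="ignore"):
        cov_pct = sbar / (r * dxdy)
        mean_pct = d_xy / (r * dxdy)

    data = {
        "gene_x": [subset[i] for i in iu[0]],
        "gene_y": [subset[j] for j in iu[1]],
        "r": r,
        "sbar_xy": sbar,
        "d_xy": d_xy,
        "d_x": np.repeat(d_x, len(subset)).reshape(len(subset), len(subset))[iu],
        "d_y": np.tile(d_x, (len(subset), 1))[iu],
        "tau_hat": tau_hat,
        "cov_pct": cov_pct,
        "mean_pct": mean_pct,
        "r_bar": pooled.within_avg_r[iu],
        "B_r": pooled.bias_pooled[iu],
        "B_rbar": pooled.bias_within_avg[iu],
    }
    if residual_branch is not None:
        data["r_star"] = residual_branch.pooled_r[iu]
        data["r_bar_star"] = residual_branch.within_avg_r[iu]
        data["B_rstar"] = residual_branch.bias_pooled[iu]
        data["B_rbarstar"] = residual_branch.bias_within_avg[iu]
    pairs = pd.DataFrame(data)

    bias_rows = {
        "B(r)": _five_number(pairs["B_r"].to_numpy()),
        "B(rbar)": _five_number(pairs["B_rbar"].to_numpy()),
    }
    if residual_branch is not None:
        bias_rows["B(r_star)"] = _five_number(pairs["B_rstar"].to_numpy())
        bias_rows["B(rbar_star)"] = _five_number(pairs["B_rbarstar"].to_numpy())
    bias_summary = pd.DataFrame(bias_rows).T
    bias_summary.index.name = "estimator"

    profile = residual_error_profile(r, tau_hat)
    strong = np.abs(r) >= config.strong_threshold
    defined = np.isfinite(r) & np.isfinite(d_xy)
    strong_defined = strong & defined
    if strong_defined.any():
        sign_agreement = float(
            np.mean(np.sign(r[strong_defined]) == np.sign(d_xy[strong_defined]))
        )
        cov_pct_median = float(np.nanmedian(cov_pct[strong_defined]) * 100.0)
        mean_pct_median = float(np.nanmedian(mean_pct[strong_defined]) * 100.0)
    else:
        sign_agreement = math.nan
        cov_pct_median = mean_pct_median = math.nan

    summary = {
        "n_genes_analyzed": len(subset),
        "n_pairs": int(len(pairs)),
        "n_excluded_genes": len(excluded),
        "n_groups_pooled_branch": pooled.n_groups_used,
        "strong_threshold": config.strong_threshold,
        "n_strong_pairs": int(strong.sum()),
        "sign_agreement_rate": sign_agreement,
        "cov_pct_median_strong": cov_pct_median,
        "mean_pct_median_strong": mean_pct_median,
        "r_range": [float(np.nanmin(r)), float(np.nanmax(r))],
        "tau_hat_range": [float(np.nanmin(tau_hat)), float(np.nanmax(tau_hat))],
        "r_mean": float(np.nanmean(r)),
        "residual_error_mean_negative": profile.mean_negative,
        "residual_error_mean_positive": profile.mean_positive,
        "residual_error_bimodal": bool(profile.bimodal),
        "r_histogram": _fd_histogram(r),
        "residual_branch_skipped": residual_branch is None,
        "convention": config.convention,
        "bias_variant": config.bias_variant,
        "seed": config.seed,
    }
    if residual_branch is not None:
        rs = pairs["r_star"].to_numpy()
        summary["r_star_range"] = [float(np.nanmin(rs)), float(np.nanmax(rs))]
        summary["corr_r_star_vs_rbar_star"] = _finite_corr(
            rs, pairs["r_bar_star"].to_numpy()
        )
    summary["corr_r_vs_rbar"] = _finite_corr(r, pairs["r_bar"].to_numpy())

    return AnalysisResult(
        pairs=pairs,
        bias_summary=bias_summary,
        summary=summary,
        residual_profile=profile,
        dropped_columns=rm.dropped,
        excluded_genes=excluded,
    )


def _finite_corr(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3 or a[ok].std() == 0 or b[ok].std() == 0:
        return math.nan
    return float(np.corrcoef(a[ok], b[ok])[0, 1])
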