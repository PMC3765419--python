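"""Sample-side estimators for pooled-correlation diagnostics.

Given observations of one gene pair split into groups, this module
computes per-group sample statistics, the plug-in decomposition
``tau_hat = (sbar_xy + d_xy) / (d_x d_y)`` of the pooled Pearson
coefficient into a within-group covariance part and a between-group
mean-difference part, the Hunter-Schmidt size-weighted average of
within-group correlations, a weighted mean-squared-deviation bias
metric, and the classical small-sample bias of the Pearson estimator.

With maximum-likelihood (n-denominator) group statistics and weights
``lam_i = n_i / sum n``, ``tau_hat`` is algebraically identical to the
pooled Pearson coefficient (law of total covariance); with unbiased
(n-1) statistics the two differ by O(1/n), which is what makes the
residual error ``r - tau_hat`` a useful diagnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .exceptions import InvalidParameterError, UndefinedCorrelationError

Convention = Literal["unbiased", "ml"]
BiasVariant = Literal["weighted_msd", "as_printed"]

#: relative tolerance for the internal decomposition identity
IDENTITY_RTOL = 1e-10


@dataclass(frozen=True)
class PairedSampleGroup:
    """Aligned observations of one gene pair within one group."""

    values_x: np.ndarray
    values_y: np.ndarray
    group_label: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.values_x, dtype=float)
        y = np.asarray(self.values_y, dtype=float)
        object.__setattr__(self, "values_x", x)
        object.__setattr__(self, "values_y", y)
        if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
            raise InvalidParameterError("values_x and values_y must be aligned 1-d sequences")
        if len(x) < 2:
            raise InvalidParameterError("a group needs at least 2 observations")
        if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
            raise InvalidParameterError("missing/non-finite values are a pipeline responsibility")

    def __len__(self) -> int:
        return len(self.values_x)


@dataclass(frozen=True)
class GroupSampleStats:
    """Sample moments of one gene pair within one group.

    ``convention`` records the variance denominator: ``"unbiased"``
    (n-1, the default everywhere in the pipeline) or ``"ml"`` (n, the
    maximum-likelihood form under which the decomposition reproduces the
    pooled Pearson coefficient exactly).
    """

    mean_x: float
    mean_y: float
    var_x: float
    var_y: float
    cov_xy: float
    n: int
    convention: Convention = "unbiased"


@dataclass(frozen=True)
class PooledDecompositionEstimate:
    """Plug-in decomposition of a pooled correlation from group stats.

    ``cov_term`` is sbar_xy (weighted average of within-group sample
    covariances), ``mean_diff_term`` is d_xy (weighted cross products of
    pairwise group-mean differences); ``tau_hat = (cov_term +
    mean_diff_term) / (d_x d_y)``.  ``cov_pct``/``mean_pct`` are each
    term divided by ``ref * d_x * d_y`` where ``ref`` is the supplied
    reference pooled correlation if given, else tau_hat (in which case
    they sum to exactly 1).
    """

    cov_term: float
    mean_diff_term: float
    d_x: float
    d_y: float
    tau_hat: float
    cov_pct: float
    mean_pct: float
    convention: Convention = "unbiased"


def compute_group_stats(group: PairedSampleGroup, convention: Convention = "unbiased") -> GroupSampleStats:
    """Per-group means, variances and covariance under a stated denominator."""
    if convention not in ("unbiased", "ml"):
        raise InvalidParameterError(f"unknown convention {convention!r}")
    x, y = group.values_x, group.values_y
    n = len(x)
    ddof = 1 if convention == "unbiased" else 0
    mx, my = float(x.mean()), float(y.mean())
    xc, yc = x - mx, y - my
    denom = n - ddof
    return GroupSampleStats(
        mean_x=mx,
        mean_y=my,
        var_x=float(xc @ xc) / denom,
        var_y=float(yc @ yc) / denom,
        cov_xy=float(xc @ yc) / denom,
        n=n,
        convention=convention,
    )


def pooled_pearson(groups: Sequence[PairedSampleGroup]) -> float:
    """Pearson correlation of the concatenation of all groups' observations."""
    if len(groups) == 0:
        raise InvalidParameterError("need at least one group")
    x = np.concatenate([g.values_x for g in groups])
    y = np.concatenate([g.values_y for g in groups])
    if len(x) < 3:
        raise InvalidParameterError("pooled sample must have at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(xc @ xc)
    sy = float(yc @ yc)
    if sx <= 0.0 or sy <= 0.0:
        raise UndefinedCorrelationError("constant axis in the pooled sample")
    return float(xc @ yc) / math.sqrt(sx * sy)


def _check_conventions(stats: Sequence[GroupSampleStats]) -> Convention:
    conventions = {s.convention for s in stats}
    if len(conventions) != 1:
        raise InvalidParameterError(f"mixed denominator conventions: {sorted(conventions)}")
    return stats[0].convention


def estimate_pooled_decomposition(
    stats: Sequence[GroupSampleStats],
    reference_r: float | None = None,
) -> PooledDecompositionEstimate:
    """Plug-in decomposition tau_hat from group-level sample statistics.

    Weights are ``lam_i = n_i / sum n``.  The mean-difference term is the
    literal pairwise double sum over ``i < j``; ``d_x^2`` and ``d_y^2``
    add the weighted average of group variances to the corresponding
    squared-mean-difference sums.
    """
    if len(stats) == 0:
        raise InvalidParameterError("need at least one group's statistics")
    convention = _check_conventions(stats)
    lam = np.array([s.n for s in stats], dtype=float)
    lam /= lam.sum()
    mx = np.array([s.mean_x for s in stats])
    my = np.array([s.mean_y for s in stats])

    sbar_xy = float(np.dot(lam, [s.cov_xy for s in stats]))
    w = np.multiply.outer(lam, lam)
    iu = np.triu_indices(len(stats), k=1)
    dmx = np.subtract.outer(mx, mx)[iu]
    dmy = np.subtract.outer(my, my)[iu]
    wij = w[iu]
    d_xy = float(np.sum(wij * dmx * dmy))
    d_x2 = float(np.dot(lam, [s.var_x for s in stats])) + float(np.sum(wij * dmx**2))
    d_y2 = float(np.dot(lam, [s.var_y for s in stats])) + float(np.sum(wij * dmy**2))
    if d_x2 <= 0.0 or d_y2 <= 0.0:
        raise UndefinedCorrelationError("tau_hat undefined: d_x or d_y is zero")
    d_x, d_y = math.sqrt(d_x2), math.sqrt(d_y2)
    tau_hat = (sbar_xy + d_xy) / (d_x * d_y)

    ref = tau_hat if reference_r is None else reference_r
    if ref != 0.0 and math.isfinite(ref):
        denom = ref * d_x * d_y
        cov_pct, mean_pct = sbar_xy / denom, d_xy / denom
    else:
        cov_pct = mean_pct = math.nan
    return PooledDecompositionEstimate(
        cov_term=sbar_xy,
        mean_diff_term=d_xy,
        d_x=d_x,
        d_y=d_y,
        tau_hat=tau_hat,
        cov_pct=cov_pct,
        mean_pct=mean_pct,
        convention=convention,
    )


def between_group_covariance(
    means_x: Sequence[float], means_y: Sequence[float], weights: Sequence[float]
) -> float:
    """Weighted between-group covariance sum lam_i (mx_i - mx)(my_i - my).

    Algebraically identical to the pairwise double sum used for d_xy
    (when the weights sum to one); kept as an independent cross-check.
    """
    lam = np.asarray(weights, dtype=float)
    lam = lam / lam.sum()
    mx = np.asarray(means_x, dtype=float)
    my = np.asarray(means_y, dtype=float)
    return float(np.dot(lam, (mx - np.dot(lam, mx)) * (my - np.dot(lam, my))))


def hunter_schmidt_average(
    within_r: Sequence[float], sizes: Sequence[int]
) -> float:
    """Size-weighted average of within-group correlations, rbar = sum lam_i r_i.

    NaN entries (groups where the within-group correlation is undefined,
    e.g. a constant gene) are excluded and the weights renormalized over
    the remaining groups.
    """
    r = np.asarray(within_r, dtype=float)
    n = np.asarray(sizes, dtype=float)
    if r.size == 0 or r.shape != n.shape:
        raise InvalidParameterError("within_r and sizes must be aligned and non-empty")
    keep = np.isfinite(r)
    if not keep.any():
        raise UndefinedCorrelationError("no group has a defined within-group correlation")
    lam = n[keep] / n[keep].sum()
    return float(np.dot(lam, r[keep]))


@dataclass(frozen=True)
class BiasEstimate:
    """Weighted mean squared deviation of an across-groups estimate from
    the within-group estimates; the ``as_printed`` variant additionally
    divides by the number of groups."""

    value: float
    variant: BiasVariant = "weighted_msd"


def correlation_bias_metric(
    pooled: float,
    within_r: Sequence[float],
    sizes: Sequence[int],
    variant: BiasVariant = "weighted_msd",
) -> BiasEstimate:
    """B(rho_hat) = sum lam_i (rho_hat - rho_hat_i)^2 (optionally / N)."""
    if variant not in ("weighted_msd", "as_printed"):
        raise InvalidParameterError(f"unknown bias variant {variant!r}")
    r = np.asarray(within_r, dtype=float)
    n = np.asarray(sizes, dtype=float)
    if r.size == 0 or r.shape != n.shape:
        raise InvalidParameterError("within_r and sizes must be aligned and non-empty")
    keep = np.isfinite(r)
    if not keep.any():
        raise UndefinedCorrelationError("no group has a defined within-group correlation")
    lam = n[keep] / n[keep].sum()
    value = float(np.dot(lam, (pooled - r[keep]) ** 2))
    if variant == "as_printed":
        value /= r.size
    return BiasEstimate(value=value, variant=variant)


def pearson_expected_bias(rho: float, n: int) -> float:
    """First-order small-sample bias of the Pearson estimator, rho(1-rho^2)/(2n)."""
    if abs(rho) > 1.0:
        raise InvalidParameterError(f"|rho| must be <= 1, got {rho}")
    if n < 2:
        raise InvalidParameterError("n must be >= 2")
    return rho * (1.0 - rho * rho) / (2.0 * n)


def argmax_pearson_bias() -> float:
    """The rho in [0, 1] maximizing rho(1-rho^2): root of 1 - 3 rho^2."""
    return 1.0 / math.sqrt(3.0)


@dataclass(frozen=True)
class ResidualErrorProfile:
    """Summary of per-pair residual errors r - tau_hat.

    ``bimodal`` flags the signature of estimator small-sample bias: the
    sign-split means have opposite signs and magnitudes within a factor
    of five of one another.
    """

    residuals: np.ndarray
    mean_negative: float
    mean_positive: float
    squared_residuals: np.ndarray
    pooled_r: np.ndarray
    bimodal: bool


def residual_error_profile(
    pooled_r: Sequence[float], tau_hat: Sequence[float]
) -> ResidualErrorProfile:
    """Residuals r - tau_hat with sign-split means and a bimodality flag."""
    r = np.asarray(pooled_r, dtype=float)
    t = np.asarray(tau_hat, dtype=float)
    if r.shape != t.shape:
        raise InvalidParameterError("pooled_r and tau_hat must be aligned")
    resid = r - t
    neg = resid[resid < 0]
    pos = resid[resid > 0]
    mean_neg = float(neg.mean()) if neg.size else 0.0
    mean_pos = float(pos.mean()) if pos.size else 0.0
    bimodal = (
        neg.size > 0
        and pos.size > 0
        and mean_neg < 0 < mean_pos
        and max(mean_pos, -mean_neg) <= 5.0 * min(mean_pos, -mean_neg)
    )
    return ResidualErrorProfile(
        residuals=resid,
        mean_negative=mean_neg,
        mean_positive=mean_pos,
        squared_residuals=resid**2,
        pooled_r=r,
        bimodal=bimodal,
    )


def stats_from_groups(
    groups: Sequence[PairedSampleGroup], convention: Convention = "unbiased"
) -> list[GroupSampleStats]:
    """Convenience: per-group statistics for a sequence of groups."""
    return [compute_group_stats(g, convention) for g in groups]
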