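"""Asymptotic pooled Pearson correlation for N heterogeneous groups.

When bivariate-normal observations from ``N`` groups with group-specific
means and covariance matrices are concatenated into one sample ("melting
pot"), the Pearson coefficient of the pool converges, as the group sizes
grow, not to any within-group correlation but to a mixture

    tau = (sum_i lam_i * sigma_xy_i
           + sum_{i<j} lam_i lam_j (mu_x_i - mu_x_j)(mu_y_i - mu_y_j))
          / (delta_x * delta_y)

with weights ``lam_i = n_i / sum n_j`` and scale terms ``delta_x``,
``delta_y`` that absorb both the weighted average of variances and the
weighted squares of mean differences.  The numerator splits the pooled
coefficient into a within-group covariance component and a between-group
mean-difference component; the latter can dominate (ecological fallacy)
or even flip the sign of every within-group association (Simpson's
paradox).

This module evaluates the limit and its decomposition exactly from
population parameters, plus the closed forms the three Monte-Carlo
scenario families reduce to.  Everything here is pure computation on
small parameter sets; no data are simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .exceptions import InvalidParameterError, UndefinedCorrelationError

#: relative tolerance for parameter-validity checks (Cauchy-Schwarz etc.)
PARAM_RTOL = 1e-9
#: relative tolerance at which closed forms must agree with the general limit
EQUIV_RTOL = 1e-10


@dataclass(frozen=True)
class GroupParams:
    """Population parameters of one gene pair within one group.

    Means are on the (log2-like) expression scale, variances in squared
    units; ``size`` is the number of observations the group contributes
    to the pool and determines its weight.
    """

    mean_x: float
    mean_y: float
    var_x: float
    var_y: float
    cov_xy: float
    size: int = 1

    def __post_init__(self) -> None:
        if self.var_x < 0 or self.var_y < 0:
            raise InvalidParameterError(
                f"negative variance: var_x={self.var_x}, var_y={self.var_y}"
            )
        bound = self.var_x * self.var_y
        if self.cov_xy**2 > bound * (1.0 + PARAM_RTOL) + PARAM_RTOL:
            raise InvalidParameterError(
                f"cov_xy^2={self.cov_xy**2} exceeds var_x*var_y={bound} "
                "(Cauchy-Schwarz violation)"
            )
        if int(self.size) != self.size or self.size < 1:
            raise InvalidParameterError(f"group size must be a positive integer, got {self.size}")

    @property
    def correlation(self) -> float:
        """Within-group correlation; undefined for a degenerate axis."""
        denom = math.sqrt(self.var_x * self.var_y)
        if denom == 0.0:
            raise UndefinedCorrelationError("zero variance: within-group correlation undefined")
        return self.cov_xy / denom

    def swapped(self) -> "GroupParams":
        """The same group with the x and y roles exchanged."""
        return GroupParams(self.mean_y, self.mean_x, self.var_y, self.var_x, self.cov_xy, self.size)


class GroupParamsSet:
    """An ordered collection of :class:`GroupParams` with derived weights.

    Weights default to ``lam_i = n_i / sum n_j``.  An explicit-weights
    entry point (:meth:`from_weights`) renormalizes any positive weights
    through the same code path.
    """

    def __init__(self, groups: Sequence[GroupParams], weights: Sequence[float] | None = None):
        if len(groups) < 1:
            raise InvalidParameterError("need at least one group")
        self._groups = tuple(groups)
        if weights is None:
            raw = np.array([g.size for g in self._groups], dtype=float)
        else:
            raw = np.asarray(weights, dtype=float)
            if raw.shape != (len(self._groups),):
                raise InvalidParameterError("weights must align with groups")
            if np.any(raw <= 0):
                raise InvalidParameterError("weights must be strictly positive")
        self._weights = raw / raw.sum()

    @classmethod
    def from_weights(
        cls, groups: Sequence[GroupParams], weights: Sequence[float]
    ) -> "GroupParamsSet":
        return cls(groups, weights=weights)

    def __len__(self) -> int:
        return len(self._groups)

    def __getitem__(self, i: int) -> GroupParams:
        return self._groups[i]

    def __iter__(self) -> Iterator[GroupParams]:
        return iter(self._groups)

    @property
    def groups(self) -> tuple[GroupParams, ...]:
        return self._groups

    @property
    def weights(self) -> np.ndarray:
        """lam_i, normalized to sum to one."""
        return self._weights.copy()

    # parameter arrays, in group order
    @property
    def mean_x(self) -> np.ndarray:
        return np.array([g.mean_x for g in self._groups])

    @property
    def mean_y(self) -> np.ndarray:
        return np.array([g.mean_y for g in self._groups])

    @property
    def var_x(self) -> np.ndarray:
        return np.array([g.var_x for g in self._groups])

    @property
    def var_y(self) -> np.ndarray:
        return np.array([g.var_y for g in self._groups])

    @property
    def cov_xy(self) -> np.ndarray:
        return np.array([g.cov_xy for g in self._groups])

    @property
    def sizes(self) -> np.ndarray:
        return np.array([g.size for g in self._groups], dtype=int)

    def swapped(self) -> "GroupParamsSet":
        return GroupParamsSet([g.swapped() for g in self._groups], weights=self._weights)


@dataclass(frozen=True)
class AsymptoticDecomposition:
    """The pooled-correlation limit tau and its two numerator components.

    ``cov_term`` is the weighted average of within-group covariances;
    ``mean_diff_term`` the weighted sum of cross products of pairwise
    group-mean differences.  ``tau * delta_x * delta_y`` equals their sum
    exactly.  The fractions are each term divided by ``tau*delta_x*delta_y``
    (NaN when tau is zero).
    """

    tau: float
    cov_term: float
    mean_diff_term: float
    delta_x: float
    delta_y: float
    cov_fraction: float = field(default=math.nan)
    mean_fraction: float = field(default=math.nan)


def _pairwise_cross(weights: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """sum_{i<j} lam_i lam_j (a_i - a_j)(b_i - b_j), by explicit double sum."""
    da = np.subtract.outer(a, a)
    db = np.subtract.outer(b, b)
    w = np.multiply.outer(weights, weights)
    iu = np.triu_indices(len(a), k=1)
    return float(np.sum(w[iu] * da[iu] * db[iu]))


def asymptotic_pooled_correlation(groups: GroupParamsSet) -> AsymptoticDecomposition:
    """Probability limit of the pooled Pearson coefficient and its split.

    Parameters
    ----------
    groups
        Population parameters of every group, with weights derived from
        group sizes (or explicitly supplied).

    Returns
    -------
    AsymptoticDecomposition
        tau together with the covariance and mean-difference components
        of the numerator and the scale terms delta_x, delta_y.

    Raises
    ------
    UndefinedCorrelationError
        If delta_x or delta_y vanishes (all variances zero with identical
        means): the limit is undefined, never reported as 0 or NaN.
    """
    lam = groups.weights
    mx, my = groups.mean_x, groups.mean_y

    cov_term = float(np.dot(lam, groups.cov_xy))
    mean_diff_term = _pairwise_cross(lam, mx, my)

    # sums of non-negative contributions: zero exactly when every variance is
    # zero and the axis means coincide
    delta_x2 = float(np.dot(lam, groups.var_x)) + _pairwise_cross(lam, mx, mx)
    delta_y2 = float(np.dot(lam, groups.var_y)) + _pairwise_cross(lam, my, my)
    if delta_x2 <= 0.0 or delta_y2 <= 0.0:
        raise UndefinedCorrelationError(
            "pooled correlation undefined: a pooled scale term delta is zero"
        )
    delta_x = math.sqrt(delta_x2)
    delta_y = math.sqrt(delta_y2)
    tau = (cov_term + mean_diff_term) / (delta_x * delta_y)

    if tau != 0.0:
        denom = tau * delta_x * delta_y
        cov_frac = cov_term / denom
        mean_frac = mean_diff_term / denom
    else:
        cov_frac = mean_frac = math.nan
    return AsymptoticDecomposition(
        tau=tau,
        cov_term=cov_term,
        mean_diff_term=mean_diff_term,
        delta_x=delta_x,
        delta_y=delta_y,
        cov_fraction=cov_frac,
        mean_fraction=mean_frac,
    )


def asymptotic_pooled_correlation_common_means(
    groups: GroupParamsSet, mean_tol: float = 1e-8
) -> float:
    """Pooled-correlation limit when groups share means (heteroskedasticity only).

    Reduces to ``sum lam_i sigma_xy_i / sqrt(sum lam_i var_x_i * sum lam_i
    var_y_i)``; agrees with :func:`asymptotic_pooled_correlation` on the
    same input.

    Raises
    ------
    InvalidParameterError
        If the group means are not equal within ``mean_tol`` (misuse of
        the special case).
    """
    mx, my = groups.mean_x, groups.mean_y
    spread = max(np.ptp(mx), np.ptp(my))
    scale = 1.0 + max(float(np.max(np.abs(mx))), float(np.max(np.abs(my))))
    if spread > mean_tol * scale:
        raise InvalidParameterError(
            f"common-means special case requires equal group means (spread {spread:g})"
        )
    lam = groups.weights
    vx = float(np.dot(lam, groups.var_x))
    vy = float(np.dot(lam, groups.var_y))
    if vx <= 0 or vy <= 0:
        raise UndefinedCorrelationError("zero pooled variance on an axis")
    return float(np.dot(lam, groups.cov_xy)) / math.sqrt(vx * vy)


def closed_form_mean_shift(alpha: float, lam: float) -> float:
    """Pooled-correlation limit of the mean-shift scenario.

    Scenario: N = 1/lam groups with zero within-group correlation and
    identity covariance; group 1 has mean (alpha, 0), group 2 (0, alpha),
    the rest (2, 2).

        tau = (-lam^2 alpha^2 - 4 lam (1-2 lam)(alpha-2))
              / (lam^2 alpha^2 + lam (1-2 lam)(alpha-2)^2 + 4 lam (1-2 lam) + 1)

    Positive for alpha < 2, negative for alpha > 2, near zero at alpha = 2.
    """
    if not (0.0 < lam <= 0.5):
        raise InvalidParameterError(f"weight lam must lie in (0, 0.5], got {lam}")
    l2 = lam * lam
    q = lam * (1.0 - 2.0 * lam)
    num = -l2 * alpha**2 - 4.0 * q * (alpha - 2.0)
    den = l2 * alpha**2 + q * (alpha - 2.0) ** 2 + 4.0 * q + 1.0
    return num / den


def pair_distance_sum(N: int) -> int:
    """S(N) = sum_{i<j} (i-j)^2 = sum_{d=1}^{N-1} (N-d) d^2, exactly."""
    if int(N) != N or N < 1:
        raise InvalidParameterError(f"N must be a positive integer, got {N}")
    N = int(N)
    return sum((N - d) * d * d for d in range(1, N))


def closed_form_simpson(rho: float, N: int) -> float:
    """Pooled-correlation limit of the Simpson-design scenario.

    Scenario: N groups with means (i, N+1-i), unit variances and common
    within-group correlation rho.  With S = S(N) and lam = 1/N,

        tau = (rho - S/N^2) / (1 + S/N^2)

    which approaches -1 as N grows, whatever the sign of rho.
    """
    if abs(rho) > 1.0:
        raise InvalidParameterError(f"|rho| must be <= 1, got {rho}")
    s = pair_distance_sum(N) / (N * N)
    return (rho - s) / (1.0 + s)


def closed_form_heteroskedastic(rho: float, sigmas_x: Sequence[float]) -> float:
    """Pooled-correlation limit of the heteroskedastic scenario.

    Scenario: equal group means, gene y with unit variance, gene x with
    standard deviation ``sigmas_x[i]`` in group i, within-group
    correlation rho everywhere.  The limit is linear in rho with slope
    ``mean(sigma) / sqrt(mean(sigma^2)) <= 1`` (Jensen), attenuating the
    pooled coefficient toward zero relative to rho.
    """
    if abs(rho) > 1.0:
        raise InvalidParameterError(f"|rho| must be <= 1, got {rho}")
    s = np.asarray(sigmas_x, dtype=float)
    if s.size == 0 or np.any(s <= 0):
        raise InvalidParameterError("all sigmas must be strictly positive")
    return rho * float(s.mean()) / math.sqrt(float((s**2).mean()))
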