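"""Monte-Carlo case studies for pooled-correlation behavior.

Five scenario families, each drawing bivariate-normal observations per
group, pooling them and averaging the pooled Pearson coefficient (and
the size-weighted mean of within-group coefficients) over repetitions:

``control``
    identical N(0, I) groups — the pooled coefficient averages to zero.
``mean_shift``
    zero within-group correlation, two groups with opposed single-axis
    mean shifts alpha; the pool acquires a spurious correlation whose
    sign flips at alpha = 2.
``simpson``
    group means on the anti-diagonal (i, N+1-i) with common positive
    within-group correlation; the pool is strongly negative (Simpson's
    paradox).
``hetero_zero_cov``
    equal means, zero covariances, group-specific variances — the pool
    stays near zero despite heteroskedasticity.
``heteroskedastic``
    equal means, gene-x standard deviation i in group i; the pooled
    coefficient is attenuated linearly (slope sigma-bar / rms sigma).

plus an experiment measuring the mean squared error between the
asymptotic limit tau and its plug-in estimate tau_hat as the per-group
sample size grows.

Repetitions within one grid cell are drawn vectorized from a per-cell
child stream of the root seed, so cells are independent and each cell
is re-runnable in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .exceptions import InvalidParameterError
from .theory import (
    GroupParams,
    GroupParamsSet,
    asymptotic_pooled_correlation,
    closed_form_heteroskedastic,
    closed_form_mean_shift,
    closed_form_simpson,
)

SCENARIOS = (
    "control",
    "mean_shift",
    "simpson",
    "hetero_zero_cov",
    "heteroskedastic",
    "estimator_mse",
)

_DEFAULT_ALPHA_GRID = tuple(float(a) for a in np.arange(-10.0, 10.0 + 1e-9, 0.5))
_DEFAULT_RHO_GRID = tuple(float(r) for r in np.round(np.arange(-0.9, 0.9 + 1e-9, 0.1), 10))
_DEFAULT_N_GRID = tuple(range(10, 101, 10))
_DEFAULT_NI_GRID = tuple(range(10, 101, 10))


@dataclass(frozen=True)
class ScenarioConfig:
    """Grid configuration of one simulation scenario.

    Grids default to the study's published ranges: alpha in [-10, 10]
    step 0.5, rho in {-0.9, ..., 0.9} step 0.1, N in {10, 20, ..., 100}
    (equivalently lambda = 1/N in [0.01, 0.1]), n_per_group = 10, 1000
    repetitions.  ``ni_grid`` is used only by the estimator-MSE
    experiment (per-group sample sizes 10..100 at fixed N).
    """

    scenario: str
    alpha_grid: tuple[float, ...] = _DEFAULT_ALPHA_GRID
    rho_grid: tuple[float, ...] = _DEFAULT_RHO_GRID
    N_grid: tuple[int, ...] = _DEFAULT_N_GRID
    n_per_group: int = 10
    reps: int = 1000
    seed: int = 0
    ni_grid: tuple[int, ...] = _DEFAULT_NI_GRID
    mse_rho: float = 0.5
    mse_N: int = 20

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise InvalidParameterError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        if self.reps < 1 or self.n_per_group < 1:
            raise InvalidParameterError("reps and n_per_group must be >= 1")
        for grid, name in ((self.alpha_grid, "alpha_grid"), (self.rho_grid, "rho_grid"),
                           (self.N_grid, "N_grid"), (self.ni_grid, "ni_grid")):
            if len(grid) == 0:
                raise InvalidParameterError(f"{name} must be non-empty")
        if any(N < 2 for N in self.N_grid):
            raise InvalidParameterError("N_grid entries must be >= 2")
        if any(abs(r) > 1 for r in self.rho_grid):
            raise InvalidParameterError("rho_grid entries must lie in [-1, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        for key in ("alpha_grid", "rho_grid", "N_grid", "ni_grid"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SimulationCell:
    """Repetition-averaged results at one grid point."""

    alpha: float | None
    rho: float | None
    N: int
    mean_pooled_r: float
    mean_within_avg_r: float
    closed_form_tau: float
    reps_used: int


@dataclass
class SimulationTable:
    """All cells of one scenario run plus grid-level summaries."""

    scenario: str
    config: ScenarioConfig
    cells: list[SimulationCell] = field(default_factory=list)

    @property
    def min_pooled_r(self) -> float:
        return min(c.mean_pooled_r for c in self.cells)

    @property
    def max_pooled_r(self) -> float:
        return max(c.mean_pooled_r for c in self.cells)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([asdict(c) for c in self.cells])
        df.insert(0, "scenario", self.scenario)
        df["n_per_group"] = self.config.n_per_group
        return df

    def summary(self) -> dict:
        """Grid extremes plus, for rho-indexed scenarios, the OLS slope
        (with intercept, unweighted, all cells pooled) of the averaged
        pooled r — and of the averaged within-group mean r — on rho."""
        out: dict = {
            "scenario": self.scenario,
            "min_pooled_r": self.min_pooled_r,
            "max_pooled_r": self.max_pooled_r,
            "min_within_avg_r": min(c.mean_within_avg_r for c in self.cells),
            "max_within_avg_r": max(c.mean_within_avg_r for c in self.cells),
            "n_cells": len(self.cells),
            "reps": self.config.reps,
        }
        rhos = [c.rho for c in self.cells if c.rho is not None]
        if len(set(rhos)) > 1:
            r = np.array([c.mean_pooled_r for c in self.cells])
            w = np.array([c.mean_within_avg_r for c in self.cells])
            x = np.array(rhos, dtype=float)
            out["ols_slope_pooled_r_vs_rho"] = float(sps.linregress(x, r).slope)
            out["ols_slope_within_avg_r_vs_rho"] = float(sps.linregress(x, w).slope)
        return out

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.10g")

    def write_summary_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def build_group_params(
    scenario: str,
    *,
    alpha: float | None = None,
    rho: float | None = None,
    N: int | None = None,
    n_per_group: int = 10,
) -> GroupParamsSet:
    """Population parameters of one grid point of a scenario family."""
    if N is None or N < 2:
        raise InvalidParameterError("N must be given and >= 2")
    if scenario == "control":
        groups = [GroupParams(0.0, 0.0, 1.0, 1.0, 0.0, n_per_group) for _ in range(N)]
    elif scenario == "mean_shift":
        if alpha is None:
            raise InvalidParameterError("mean_shift needs alpha")
        means = [(alpha, 0.0), (0.0, alpha)] + [(2.0, 2.0)] * (N - 2)
        groups = [GroupParams(mx, my, 1.0, 1.0, 0.0, n_per_group) for mx, my in means]
    elif scenario == "simpson":
        if rho is None:
            raise InvalidParameterError("simpson needs rho")
        groups = [
            GroupParams(float(i), float(N + 1 - i), 1.0, 1.0, rho, n_per_group)
            for i in range(1, N + 1)
        ]
    elif scenario == "heteroskedastic":
        if rho is None:
            raise InvalidParameterError("heteroskedastic needs rho")
        groups = [
            GroupParams(2.0, 2.0, float(i * i), 1.0, rho * i, n_per_group)
            for i in range(1, N + 1)
        ]
    elif scenario == "hetero_zero_cov":
        groups = [
            GroupParams(2.0, 2.0, float(i * i), float((N + 1 - i) ** 2), 0.0, n_per_group)
            for i in range(1, N + 1)
        ]
    else:
        raise InvalidParameterError(f"no parameter template for scenario {scenario!r}")
    return GroupParamsSet(groups)


def closed_form_tau(scenario: str, *, alpha=None, rho=None, N=None) -> float:
    """The matching closed-form asymptotic tau for a grid point."""
    if scenario in ("control", "hetero_zero_cov"):
        return 0.0
    if scenario == "mean_shift":
        return closed_form_mean_shift(alpha, 1.0 / N)
    if scenario == "simpson":
        return closed_form_simpson(rho, N)
    if scenario == "heteroskedastic":
        return closed_form_heteroskedastic(rho, np.arange(1, N + 1, dtype=float))
    raise InvalidParameterError(f"no closed form for scenario {scenario!r}")


def _group_arrays(params: GroupParamsSet):
    """Means, Cholesky factors, sizes and pooled weights as arrays."""
    mus = np.column_stack([params.mean_x, params.mean_y])
    covs = np.empty((len(params), 2, 2))
    covs[:, 0, 0] = params.var_x
    covs[:, 1, 1] = params.var_y
    covs[:, 0, 1] = covs[:, 1, 0] = params.cov_xy
    # per-group Cholesky of a 2x2, robust to zero variance
    chols = np.zeros_like(covs)
    sx = np.sqrt(covs[:, 0, 0])
    chols[:, 0, 0] = sx
    with np.errstate(invalid="ignore", divide="ignore"):
        c10 = np.where(sx > 0, covs[:, 1, 0] / np.where(sx > 0, sx, 1.0), 0.0)
    chols[:, 1, 0] = c10
    chols[:, 1, 1] = np.sqrt(np.maximum(covs[:, 1, 1] - c10**2, 0.0))
    sizes = params.sizes
    return mus, chols, sizes


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r along axis 1 for matching 2-d arrays (reps, n)."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", xc, yc)
    den = np.sqrt(np.einsum("ij,ij->i", xc, xc) * np.einsum("ij,ij->i", yc, yc))
    return num / den


def _simulate_cell(params: GroupParamsSet, reps: int, rng: np.random.Generator):
    """Vectorized repetitions for one grid point.

    Returns the per-rep pooled Pearson r and size-weighted within-group
    average r as arrays of length ``reps``.
    """
    mus, chols, sizes = _group_arrays(params)
    total = int(sizes.sum())
    z = rng.standard_normal((reps, total, 2))
    starts = np.concatenate([[0], np.cumsum(sizes)])
    x = np.empty((reps, total))
    y = np.empty((reps, total))
    within = np.empty((reps, len(params)))
    lam = sizes / sizes.sum()
    for g in range(len(params)):
        sl = slice(starts[g], starts[g + 1])
        zx = z[:, sl, 0]
        zy = z[:, sl, 1]
        xg = mus[g, 0] + chols[g, 0, 0] * zx
        yg = mus[g, 1] + chols[g, 1, 0] * zx + chols[g, 1, 1] * zy
        x[:, sl] = xg
        y[:, sl] = yg
        within[:, g] = _pearson_rows(xg, yg)
    pooled = _pearson_rows(x, y)
    within_avg = within @ lam
    return pooled, within_avg


def simulate_rep(params: GroupParamsSet, seed: int | np.random.Generator) -> tuple[float, float]:
    """One repetition: draw every group, pool, return (pooled r, weighted
    within-group average r).  Deterministic given the seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pooled, within_avg = _simulate_cell(params, 1, rng)
    return float(pooled[0]), float(within_avg[0])


def _grid_points(config: ScenarioConfig) -> list[dict]:
    s = config.scenario
    if s == "mean_shift":
        return [{"alpha": float(a), "rho": None, "N": int(N)}
                for a in config.alpha_grid for N in config.N_grid]
    if s in ("simpson", "heteroskedastic"):
        return [{"alpha": None, "rho": float(r), "N": int(N)}
                for r in config.rho_grid for N in config.N_grid]
    if s in ("control", "hetero_zero_cov"):
        return [{"alpha": None, "rho": None, "N": int(N)} for N in config.N_grid]
    raise InvalidParameterError(f"run_scenario does not handle scenario {s!r}")


def run_scenario(config: ScenarioConfig) -> SimulationTable:
    """Run every grid cell of a scenario, averaging over repetitions.

    Each cell gets its own child stream of the root seed (SeedSequence
    spawn in grid order), so results are reproducible cell by cell.
    """
    points = _grid_points(config)
    children = np.random.SeedSequence(config.seed).spawn(len(points))
    table = SimulationTable(scenario=config.scenario, config=config)
    for point, child in zip(points, children):
        params = build_group_params(
            config.scenario,
            alpha=point["alpha"],
            rho=point["rho"],
            N=point["N"],
            n_per_group=config.n_per_group,
        )
        rng = np.random.default_rng(child)
        try:
            pooled, within_avg = _simulate_cell(params, config.reps, rng)
        except FloatingPointError as exc:  # pragma: no cover - resample-or-fail: fail
            raise RuntimeError(f"degenerate draw at grid point {point}") from exc
        table.cells.append(
            SimulationCell(
                alpha=point["alpha"],
                rho=point["rho"],
                N=point["N"],
                mean_pooled_r=float(pooled.mean()),
                mean_within_avg_r=float(within_avg.mean()),
                closed_form_tau=closed_form_tau(
                    config.scenario, alpha=point["alpha"], rho=point["rho"], N=point["N"]
                ),
                reps_used=config.reps,
            )
        )
    return table


def estimator_mse_experiment(config: ScenarioConfig) -> pd.DataFrame:
    """Mean squared error between tau and its plug-in estimate tau_hat
    versus the per-group sample size n_i.

    Generating family: the heteroskedastic scenario at ``config.mse_rho``
    with ``config.mse_N`` groups.  For each n_i in ``config.ni_grid``,
    draws grouped data ``reps`` times, computes tau_hat from unbiased
    group sample statistics, and averages the squared gap to the
    asymptotic tau of the generating parameters.
    """
    if config.scenario != "estimator_mse":
        raise InvalidParameterError("config.scenario must be 'estimator_mse'")
    N = config.mse_N
    rho = config.mse_rho
    params = build_group_params("heteroskedastic", rho=rho, N=N, n_per_group=config.n_per_group)
    tau = asymptotic_pooled_correlation(params).tau
    mus, chols, _ = _group_arrays(params)
    lam = np.full(N, 1.0 / N)

    children = np.random.SeedSequence(config.seed).spawn(len(config.ni_grid))
    rows = []
    for n_i, child in zip(config.ni_grid, children):
        rng = np.random.default_rng(child)
        z = rng.standard_normal((config.reps, N, n_i, 2))
        x = mus[None, :, None, 0] + chols[None, :, 0, 0, None] * z[..., 0]
        y = (
            mus[None, :, None, 1]
            + chols[None, :, 1, 0, None] * z[..., 0]
            + chols[None, :, 1, 1, None] * z[..., 1]
        )
        mx = x.mean(axis=2)
        my = y.mean(axis=2)
        xc = x - mx[:, :, None]
        yc = y - my[:, :, None]
        denom = n_i - 1  # unbiased group statistics
        cov = np.einsum("rgn,rgn->rg", xc, yc) / denom
        vx = np.einsum("rgn,rgn->rg", xc, xc) / denom
        vy = np.einsum("rgn,rgn->rg", yc, yc) / denom
        sbar = cov @ lam
        # between-group covariance identity for the pairwise double sum
        mxb = mx @ lam
        myb = my @ lam
        d_xy = np.einsum("rg,g->r", (mx - mxb[:, None]) * (my - myb[:, None]), lam)
        d_x2 = vx @ lam + np.einsum("rg,g->r", (mx - mxb[:, None]) ** 2, lam)
        d_y2 = vy @ lam + np.einsum("rg,g->r", (my - myb[:, None]) ** 2, lam)
        tau_hat = (sbar + d_xy) / np.sqrt(d_x2 * d_y2)
        rows.append({"n_i": int(n_i), "mse": float(np.mean((tau_hat - tau) ** 2)),
                     "reps": config.reps})
    return pd.DataFrame(rows)
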