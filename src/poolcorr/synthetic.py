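"""Synthetic grouped expression data with known ground truth.

Emulates the structure of a multi-experiment stress compendium: 19
groups (nine stresses x {root, shoot} plus one light/seedlings group),
each holding 12-18 treatment-by-time conditions with 1-3 biological
replicates.  Values are multivariate normal within a group — a
group-specific mean vector plus a group-specific covariance given
either explicitly (two-gene models) or through a low-rank factor
specification (loadings x factors + idiosyncratic noise) that is
positive semi-definite by construction and scales to hundreds of genes.

The generator records the exact generating parameters (GroundTruth), so
estimator-recovery and end-to-end pipeline tests can compare against
the implied asymptotic pooled correlation of any gene pair, both at
replicate-column level and at condition-mean level (where covariances
shrink by the average reciprocal replicate count of the group).

Randomness: every stream is keyed as ``default_rng([seed, tag, ...])``
with per-group factor streams and per-(group, gene) noise/parameter
streams, so enlarging the gene set never perturbs existing columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError
from .theory import GroupParams, GroupParamsSet, asymptotic_pooled_correlation

_STRESSES = (
    "cold", "genotoxic", "osmotic", "salt", "uvb",
    "wound", "drought", "heat", "oxidative",
)

#: condition counts per group in the emulated compendium (19 groups)
_TABLE_CONDITIONS = {
    "cold_root": 12, "cold_shoot": 12,
    "genotoxic_root": 12, "genotoxic_shoot": 12,
    "osmotic_root": 12, "osmotic_shoot": 12,
    "salt_root": 12, "salt_shoot": 12,
    "uvb_root": 14, "uvb_shoot": 14,
    "wound_root": 14, "wound_shoot": 14,
    "drought_root": 14, "drought_shoot": 14,
    "heat_root": 18, "heat_shoot": 16,
    "oxidative_root": 12, "oxidative_shoot": 12,
    "light_seedlings": 16,
}
#: (group, condition index) of the two single-replicate conditions
_TABLE_SINGLETONS = (("genotoxic_root", 0), ("heat_shoot", 15))


@dataclass(frozen=True)
class ConditionDesign:
    label: str
    replicates: int

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise InvalidParameterError("replicate count must be >= 1")


@dataclass(frozen=True)
class GroupDesign:
    label: str
    conditions: tuple[ConditionDesign, ...]

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def n_replicate_columns(self) -> int:
        return sum(c.replicates for c in self.conditions)

    @property
    def n_residual_columns(self) -> int:
        return sum(c.replicates for c in self.conditions if c.replicates >= 2)


@dataclass(frozen=True)
class StudyDesign:
    """Group / condition / replicate layout of a synthetic study."""

    groups: tuple[GroupDesign, ...]

    def __post_init__(self) -> None:
        if len(self.groups) < 1:
            raise InvalidParameterError("a design needs at least one group")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise InvalidParameterError("group labels must be unique")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def condition_counts(self) -> np.ndarray:
        """n_i: condition-mean columns per group."""
        return np.array([g.n_conditions for g in self.groups])

    @property
    def replicate_counts(self) -> np.ndarray:
        """replicate columns per group (all conditions)."""
        return np.array([g.n_replicate_columns for g in self.groups])

    @property
    def residual_counts(self) -> np.ndarray:
        """n_i*: replicate columns in multi-replicate conditions."""
        return np.array([g.n_residual_columns for g in self.groups])

    @property
    def n_singleton_conditions(self) -> int:
        return sum(1 for g in self.groups for c in g.conditions if c.replicates == 1)

    def annotation(self) -> pd.DataFrame:
        """One row per replicate column: sample_id, group, condition, replicate."""
        rows = []
        for g in self.groups:
            for c in g.conditions:
                for r in range(1, c.replicates + 1):
                    rows.append(
                        {
                            "sample_id": f"{c.label}.r{r}",
                            "group": g.label,
                            "condition": c.label,
                            "replicate": r,
                        }
                    )
        return pd.DataFrame(rows)


def default_design(seed: int | None = None) -> StudyDesign:
    """The emulated 19-group compendium layout.

    Without a seed, condition counts mirror the real compendium exactly
    (254 condition means over 522 replicate columns; two singleton
    conditions, hence 520 residual columns; two replicates per condition
    except three in the light/seedlings group).  With a seed, condition
    counts are drawn uniformly from 12-18 and replicate counts from
    {2, 3}, with exactly two single-replicate conditions placed in
    distinct groups.
    """
    labels = list(_TABLE_CONDITIONS)
    if seed is None:
        groups = []
        for label in labels:
            n_cond = _TABLE_CONDITIONS[label]
            base_reps = 3 if label == "light_seedlings" else 2
            singles = {ci for gl, ci in _TABLE_SINGLETONS if gl == label}
            conds = tuple(
                ConditionDesign(f"{label}.c{j:02d}", 1 if j in singles else base_reps)
                for j in range(n_cond)
            )
            groups.append(GroupDesign(label, conds))
        return StudyDesign(tuple(groups))

    rng = np.random.default_rng([int(seed), 7])
    counts = rng.integers(12, 19, size=len(labels))
    rep_choices = [rng.integers(2, 4, size=c) for c in counts]
    gi1, gi2 = rng.choice(len(labels), size=2, replace=False)
    for gi in (gi1, gi2):
        rep_choices[gi][int(rng.integers(0, counts[gi]))] = 1
    groups = tuple(
        GroupDesign(
            label,
            tuple(
                ConditionDesign(f"{label}.c{j:02d}", int(rep_choices[i][j]))
                for j in range(counts[i])
            ),
        )
        for i, label in enumerate(labels)
    )
    return StudyDesign(groups)


@dataclass(frozen=True)
class GeneModel:
    """Per-group distribution of g genes.

    Exactly one covariance specification is set: ``pair_covs`` (shape
    (n_groups, 2, 2)) for two-gene models, or a factor specification
    ``loadings`` (n_groups, g, k) plus ``idio_sd`` (n_groups, g) giving
    the positive semi-definite group covariance L L' + diag(sd^2).
    ``mean_offsets`` (n_groups, g) shift the per-group means around the
    baseline expression level.
    """

    n_genes: int
    mean_offsets: np.ndarray
    pair_covs: np.ndarray | None = None
    loadings: np.ndarray | None = None
    idio_sd: np.ndarray | None = None
    base_mean: float = 8.0

    def __post_init__(self) -> None:
        off = np.asarray(self.mean_offsets, dtype=float)
        object.__setattr__(self, "mean_offsets", off)
        if off.ndim != 2 or off.shape[1] != self.n_genes:
            raise InvalidParameterError("mean_offsets must be (n_groups, n_genes)")
        if (self.pair_covs is None) == (self.loadings is None):
            raise InvalidParameterError("specify exactly one of pair_covs or loadings")
        if self.pair_covs is not None:
            pc = np.asarray(self.pair_covs, dtype=float)
            object.__setattr__(self, "pair_covs", pc)
            if self.n_genes != 2 or pc.shape != (off.shape[0], 2, 2):
                raise InvalidParameterError("pair_covs requires a 2-gene model, (n_groups, 2, 2)")
            det = pc[:, 0, 0] * pc[:, 1, 1] - pc[:, 0, 1] ** 2
            if np.any(pc[:, 0, 0] < 0) or np.any(det < -1e-9):
                raise InvalidParameterError("a group covariance is not positive semi-definite")
        else:
            L = np.asarray(self.loadings, dtype=float)
            sd = np.asarray(self.idio_sd, dtype=float)
            object.__setattr__(self, "loadings", L)
            object.__setattr__(self, "idio_sd", sd)
            if L.ndim != 3 or L.shape[:2] != off.shape or sd.shape != off.shape:
                raise InvalidParameterError(
                    "loadings must be (n_groups, n_genes, k) and idio_sd (n_groups, n_genes)"
                )
            if np.any(sd < 0):
                raise InvalidParameterError("idiosyncratic standard deviations must be >= 0")

    @property
    def n_groups(self) -> int:
        return self.mean_offsets.shape[0]

    @property
    def heteroskedasticity_only(self) -> bool:
        """True when every group shares the same mean vector."""
        return bool(np.ptp(self.mean_offsets, axis=0).max(initial=0.0) == 0.0)

    def group_cov(self, i: int) -> np.ndarray:
        """Implied covariance matrix of group i (genes x genes)."""
        if self.pair_covs is not None:
            return self.pair_covs[i].copy()
        L = self.loadings[i]
        return L @ L.T + np.diag(self.idio_sd[i] ** 2)

    def group_means(self, i: int) -> np.ndarray:
        return self.base_mean + self.mean_offsets[i]

    @classmethod
    def pair(
        cls,
        group_covs: Sequence[np.ndarray],
        mean_offsets: np.ndarray | None = None,
        base_mean: float = 8.0,
    ) -> "GeneModel":
        pc = np.asarray(group_covs, dtype=float)
        if mean_offsets is None:
            mean_offsets = np.zeros((pc.shape[0], 2))
        return cls(n_genes=2, mean_offsets=mean_offsets, pair_covs=pc, base_mean=base_mean)


def factor_gene_model(
    g: int,
    k: int,
    mean_shift_scale: float,
    seed: int,
    n_groups: int = 19,
    loading_scale: float = 0.6,
    idio_sd_range: tuple[float, float] = (0.3, 1.0),
    base_mean: float = 8.0,
) -> GeneModel:
    """A g-gene, k-factor model with group-specific covariances.

    Per group and gene: factor loadings drawn N(0, loading_scale^2) and
    idiosyncratic standard deviations log-uniform over ``idio_sd_range``.
    Between-group mean offsets have marginal SD ``mean_shift_scale``
    (zero gives a heteroskedasticity-only model) and a shared rank-one
    structure — a per-group score times a per-gene shift loading, plus a
    smaller independent jitter — emulating compendium-wide shifts (e.g.
    tissue or stress effects) that move many genes together; without the
    shared component no gene pair would acquire a strong pooled
    correlation from mean differences.  Parameter streams are keyed per
    group and per (group, gene), so growing g leaves earlier genes'
    parameters and columns alone.
    """
    if not (1 <= k <= g) or g < 2:
        raise InvalidParameterError("need g >= 2 and 1 <= k <= g")
    if mean_shift_scale < 0:
        raise InvalidParameterError("mean_shift_scale must be >= 0")
    lo, hi = idio_sd_range
    if not (0 < lo <= hi):
        raise InvalidParameterError("idio_sd_range must be positive and ordered")
    loadings = np.empty((n_groups, g, k))
    idio = np.empty((n_groups, g))
    offsets = np.zeros((n_groups, g))
    scores = np.array(
        [np.random.default_rng([int(seed), 13, gi]).standard_normal() for gi in range(n_groups)]
    )
    shift_loadings = np.array(
        [np.random.default_rng([int(seed), 17, gene]).standard_normal() for gene in range(g)]
    )
    for gi in range(n_groups):
        for gene in range(g):
            rng = np.random.default_rng([int(seed), 11, gi, gene])
            loadings[gi, gene] = rng.normal(0.0, loading_scale, size=k)
            idio[gi, gene] = np.exp(rng.uniform(np.log(lo), np.log(hi)))
            jitter = rng.standard_normal()
            if mean_shift_scale > 0:
                # shared rank-one shift + 30% independent jitter, scaled so
                # the marginal offset SD is mean_shift_scale
                shared = scores[gi] * shift_loadings[gene]
                offsets[gi, gene] = (
                    mean_shift_scale / np.sqrt(1.0 + 0.3**2) * (shared + 0.3 * jitter)
                )
    return GeneModel(
        n_genes=g,
        mean_offsets=offsets,
        loadings=loadings,
        idio_sd=idio,
        base_mean=base_mean,
    )


@dataclass(frozen=True)
class GroundTruth:
    """Exact generating parameters behind a synthetic matrix."""

    design: StudyDesign
    model: GeneModel

    def _cov_shrink(self) -> np.ndarray:
        """Per-group covariance factor of condition-mean columns:
        the mean reciprocal replicate count over the group's conditions."""
        return np.array(
            [np.mean([1.0 / c.replicates for c in g.conditions]) for g in self.design.groups]
        )

    def pair_group_params(
        self, gene_i: int, gene_j: int, level: str = "condition_mean"
    ) -> GroupParamsSet:
        """Implied per-group parameters of one gene pair.

        ``level="replicate"`` describes replicate columns (sizes n_i*,
        including singletons); ``level="condition_mean"`` describes
        condition-mean columns (sizes n_i, covariances shrunk by the
        average reciprocal replicate count).
        """
        if level not in ("replicate", "condition_mean"):
            raise InvalidParameterError(f"unknown level {level!r}")
        shrink = self._cov_shrink() if level == "condition_mean" else np.ones(self.design.n_groups)
        sizes = (
            self.design.condition_counts
            if level == "condition_mean"
            else self.design.replicate_counts
        )
        groups = []
        for gi in range(self.design.n_groups):
            cov = self.model.group_cov(gi)
            mu = self.model.group_means(gi)
            groups.append(
                GroupParams(
                    mean_x=float(mu[gene_i]),
                    mean_y=float(mu[gene_j]),
                    var_x=float(cov[gene_i, gene_i] * shrink[gi]),
                    var_y=float(cov[gene_j, gene_j] * shrink[gi]),
                    cov_xy=float(cov[gene_i, gene_j] * shrink[gi]),
                    size=int(sizes[gi]),
                )
            )
        return GroupParamsSet(groups)

    def pair_tau(self, gene_i: int, gene_j: int, level: str = "condition_mean") -> float:
        """Asymptotic pooled correlation of one gene pair at a level."""
        return asymptotic_pooled_correlation(self.pair_group_params(gene_i, gene_j, level)).tau

    def to_json(self, path: str | Path, pairs: Sequence[tuple[int, int]] | None = None) -> None:
        """Persist design counts and per-pair parameters/taus for a pair subset."""
        if pairs is None:
            g = self.model.n_genes
            pairs = [(i, j) for i in range(min(g, 10)) for j in range(i + 1, min(g, 10))]
        payload = {
            "n_groups": self.design.n_groups,
            "group_labels": [g.label for g in self.design.groups],
            "condition_counts": self.design.condition_counts.tolist(),
            "replicate_counts": self.design.replicate_counts.tolist(),
            "residual_counts": self.design.residual_counts.tolist(),
            "base_mean": self.model.base_mean,
            "heteroskedasticity_only": self.model.heteroskedasticity_only,
            "pairs": [
                {
                    "genes": [int(i), int(j)],
                    "tau_condition_mean": self.pair_tau(i, j, "condition_mean"),
                    "tau_replicate": self.pair_tau(i, j, "replicate"),
                }
                for i, j in pairs
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def generate_expression(
    design: StudyDesign, model: GeneModel, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw a replicate-level expression matrix for a design and model.

    Within each group, columns are i.i.d. multivariate normal draws with
    the group's mean vector and covariance; the condition layout only
    determines labels and replication.  Returns the matrix (genes x
    replicate columns), the matching annotation, and the GroundTruth.
    """
    if model.n_groups != design.n_groups:
        raise InvalidParameterError(
            f"model has {model.n_groups} groups but design has {design.n_groups}"
        )
    g = model.n_genes
    gene_ids = [f"g{i + 1:04d}" for i in range(g)]
    ann = design.annotation()
    blocks = []
    for gi, grp in enumerate(design.groups):
        ncols = grp.n_replicate_columns
        mu = model.group_means(gi)
        if model.pair_covs is not None:
            cov = model.group_cov(gi)
            rng = np.random.default_rng([int(seed), 23, gi])
            L = _psd_cholesky(cov)
            block = mu[:, None] + L @ rng.standard_normal((g, ncols))
        else:
            rng_f = np.random.default_rng([int(seed), 31, gi])
            factors = rng_f.standard_normal((model.loadings.shape[2], ncols))
            block = mu[:, None] + model.loadings[gi] @ factors
            for gene in range(g):
                rng_e = np.random.default_rng([int(seed), 37, gi, gene])
                block[gene] += model.idio_sd[gi, gene] * rng_e.standard_normal(ncols)
        blocks.append(block)
    matrix = pd.DataFrame(
        np.concatenate(blocks, axis=1), index=gene_ids, columns=ann["sample_id"].tolist()
    )
    matrix.index.name = "gene_id"
    return matrix, ann, GroundTruth(design=design, model=model)


def _psd_cholesky(cov: np.ndarray) -> np.ndarray:
    """Cholesky factor tolerant of semi-definite (rank-deficient) input."""
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(cov)
        w = np.clip(w, 0.0, None)
        return v * np.sqrt(w)
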