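"""Data reductions for grouped expression matrices.

Two reductions feed the correlation diagnostics:

* condition means — biological replicates of each treatment-by-time
  condition are averaged into one column (the "pooled" expression
  matrix whose columns are condition means); single-replicate
  conditions pass their lone value through;
* residualization — within each group a linear model with a
  condition-indicator design is fitted per gene by least squares and
  the residuals retained, which is numerically identical to subtracting
  each replicate from its condition mean.  Single-replicate conditions
  are excluded (their residual is identically zero) and logged.

Matrices are pandas DataFrames with genes as rows and samples as
columns throughout; the annotation maps every sample column to a
(group, condition, replicate) triple, conditions nesting within groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError

ANNOTATION_COLUMNS = ("group", "condition", "replicate")


def validate_annotation(matrix: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Check matrix/annotation agreement; return annotation indexed by sample id.

    Accepts an annotation with the sample id either as the index or in a
    ``sample_id`` column.  Raises :class:`DataError` naming the first
    offending sample on any mismatch.
    """
    ann = annotation.copy()
    if "sample_id" in ann.columns:
        ann = ann.set_index("sample_id")
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing_cols:
        raise DataError(f"annotation lacks required columns: {missing_cols}")
    if ann.index.duplicated().any():
        dup = ann.index[ann.index.duplicated()][0]
        raise DataError(f"sample {dup!r} annotated more than once")
    unannotated = matrix.columns.difference(ann.index)
    if len(unannotated):
        raise DataError(f"matrix column {unannotated[0]!r} has no annotation")
    extra = ann.index.difference(matrix.columns)
    if len(extra):
        raise DataError(f"annotation names sample {extra[0]!r} absent from the matrix")
    # conditions must nest within groups
    ngroups = ann.groupby("condition", sort=False)["group"].nunique()
    bad = ngroups[ngroups > 1]
    if len(bad):
        raise DataError(f"condition {bad.index[0]!r} spans more than one group")
    return ann.loc[matrix.columns]


@dataclass
class ConditionMeanMatrix:
    """Genes x conditions matrix of replicate means.

    ``replicate_counts`` records how many replicates entered each column
    (1 for pass-through singleton conditions); ``condition_groups`` maps
    each condition column to its group.
    """

    values: pd.DataFrame
    replicate_counts: pd.Series
    condition_groups: pd.Series


@dataclass
class ResidualMatrix:
    """Genes x replicate-columns matrix of within-condition residuals.

    Restricted to conditions with >= 2 replicates; ``dropped`` logs the
    excluded columns (sample_id, reason).  ``sample_groups`` maps each
    retained column to its group.
    """

    values: pd.DataFrame
    dropped: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["sample_id", "reason"]))
    sample_groups: pd.Series = field(default_factory=pd.Series)


def condition_means(
    matrix: pd.DataFrame, annotation: pd.DataFrame, log2_transform: bool = False
) -> ConditionMeanMatrix:
    """Average biological replicates into one column per condition.

    Input is assumed already normalized and on a log2-like scale; set
    ``log2_transform`` for linear-scale input.  Column order follows
    first appearance of each condition in the matrix.
    """
    ann = validate_annotation(matrix, annotation)
    values = np.log2(matrix) if log2_transform else matrix
    cond = ann["condition"]
    order = cond.drop_duplicates().tolist()
    grouped = values.T.groupby(cond, sort=False).mean().T
    grouped = grouped[order]
    counts = cond.value_counts(sort=False).reindex(order)
    groups = ann.drop_duplicates("condition").set_index("condition")["group"].reindex(order)
    return ConditionMeanMatrix(values=grouped, replicate_counts=counts, condition_groups=groups)


def residualize(
    matrix: pd.DataFrame, annotation: pd.DataFrame, log2_transform: bool = False
) -> ResidualMatrix:
    """Least-squares residuals from per-group condition-indicator models.

    Within each group, every gene's expression vector is regressed on
    indicator columns for its conditions (Y = Z b + e) and the residuals
    e-hat = Y - Z b-hat are returned; with this design b-hat holds the
    condition means, so each residual equals the value minus its
    condition's replicate mean.  Conditions with a single replicate are
    dropped beforehand and logged; a group with no multi-replicate
    condition contributes nothing (logged as well).
    """
    ann = validate_annotation(matrix, annotation)
    values = np.log2(matrix) if log2_transform else matrix

    rep_counts = ann.groupby("condition", sort=False)["group"].size()
    singleton = rep_counts[rep_counts < 2].index
    dropped_rows = [
        {"sample_id": s, "reason": "single-replicate condition"}
        for s in ann.index[ann["condition"].isin(singleton)]
    ]
    keep = ann.index[~ann["condition"].isin(singleton)]
    ann_kept = ann.loc[keep]

    blocks: list[pd.DataFrame] = []
    for grp, sub in ann_kept.groupby("group", sort=False):
        cols = sub.index
        Y = values[cols].to_numpy()  # genes x columns
        Z = pd.get_dummies(sub["condition"]).to_numpy(dtype=float)  # columns x conditions
        beta, *_ = np.linalg.lstsq(Z, Y.T, rcond=None)
        resid = Y.T - Z @ beta
        blocks.append(pd.DataFrame(resid.T, index=values.index, columns=cols))
    for grp in ann["group"].unique():
        if grp not in set(ann_kept["group"]):
            dropped_rows.append(
                {"sample_id": f"<group {grp}>", "reason": "no multi-replicate condition"}
            )
    if blocks:
        out = pd.concat(blocks, axis=1)
        out = out[[c for c in matrix.columns if c in out.columns]]
    else:
        out = pd.DataFrame(index=values.index)
    dropped = pd.DataFrame(dropped_rows, columns=["sample_id", "reason"])
    groups = ann.loc[out.columns, "group"] if len(out.columns) else pd.Series(dtype=object)
    return ResidualMatrix(values=out, dropped=dropped, sample_groups=groups)
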