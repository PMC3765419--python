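"""TSV dialect for expression matrices, annotations and reports.

Matrices: tab-separated, first column the gene id, header row of sample
ids.  Annotations: tab-separated with columns sample_id, group,
condition, replicate.  Write-then-read round trips preserve values to
full precision (17 significant digits).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .exceptions import DataError

log = logging.getLogger(__name__)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Load a genes x samples matrix, validating the dialect."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except Exception as exc:
        raise DataError(f"cannot parse expression matrix {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise DataError(f"expression matrix {path} has no sample columns")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise DataError(f"duplicate gene id {dup!r} in {path}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise DataError(f"duplicate sample id {dup!r} in {path}")
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise DataError(f"non-numeric cells in column {non_numeric[0]!r} of {path}")
    if df.isna().any().any():
        raise DataError(f"missing values in expression matrix {path}")
    log.info("loaded expression matrix %s: %d genes x %d samples", path, *df.shape)
    return df


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Load a sample annotation table (sample_id, group, condition, replicate)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    except Exception as exc:
        raise DataError(f"cannot parse annotation {path}: {exc}") from exc
    required = {"sample_id", "group", "condition", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"annotation {path} lacks columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise DataError(f"duplicate sample id {dup!r} in annotation {path}")
    log.info("loaded annotation %s: %d samples, %d groups", path, len(df), df["group"].nunique())
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=True, float_format="%.17g")


def write_annotation(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_report(df: pd.DataFrame, path: str | Path) -> None:
    """Write a per-pair report (or any tabular report) as TSV."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_summary_json(summary: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
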