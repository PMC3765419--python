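"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pandas as pd
import pytest

from poolcorr.synthetic import (
    GeneModel,
    default_design,
    factor_gene_model,
    generate_expression,
)


@pytest.fixture(scope="session")
def compendium_design():
    """The fixed 19-group layout (254 conditions / 522 replicate columns)."""
    return default_design()


@pytest.fixture(scope="session")
def mean_heterogeneous_dataset(compendium_design):
    """40 genes with strong between-group mean shifts (shift SD 3 vs
    within-group SD ~1): many strong pooled correlations driven by
    mean differences."""
    model = factor_gene_model(g=40, k=3, mean_shift_scale=3.0, seed=101)
    matrix, annotation, truth = generate_expression(compendium_design, model, seed=202)
    return matrix, annotation, truth


@pytest.fixture(scope="session")
def heteroskedastic_dataset(compendium_design):
    """30 genes, equal means across groups, group-specific covariances."""
    model = factor_gene_model(g=30, k=3, mean_shift_scale=0.0, seed=303)
    matrix, annotation, truth = generate_expression(compendium_design, model, seed=404)
    return matrix, annotation, truth


@pytest.fixture()
def worked_example_matrix():
    """Replicate-level matrix whose condition means reproduce the
    hand-checkable two-group example: group A condition means x=(0,1,2),
    y=(0,1,2); group B x=(4,5,6), y=(6,5,4).  Replicates are offset
    symmetrically (+/- 0.5 for x, -/+ 0.5 for y) so condition means are
    exact and residuals are nonzero."""
    conds = []
    values_x, values_y = [], []
    for grp, xs, ys in (("A", (0, 1, 2), (0, 1, 2)), ("B", (4, 5, 6), (6, 5, 4))):
        for j, (mx, my) in enumerate(zip(xs, ys)):
            conds.append((grp, f"{grp}.c{j}"))
            values_x += [mx - 0.5, mx + 0.5]
            values_y += [my + 0.5, my - 0.5]
    sample_ids = [f"{c}.r{r}" for _, c in conds for r in (1, 2)]
    matrix = pd.DataFrame(
        np.array([values_x, values_y]), index=["gx", "gy"], columns=sample_ids
    )
    rows = []
    for grp, c in conds:
        for r in (1, 2):
            rows.append({"sample_id": f"{c}.r{r}", "group": grp, "condition": c, "replicate": r})
    annotation = pd.DataFrame(rows)
    return matrix, annotation
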