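"""Expression normalization, reliability filtering and category scoring.

Gene expression from two section sources is normalized per gene with
the scaled robust sigmoid; genes measured in both sources are kept
when their cross-source spatial correlation reaches a reliability
threshold; each gene is correlated with a synapse-density map; and
gene categories are ranked by their "category score" — the median
absolute Spearman correlation across the category's genes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import robust_sigmoid_columns, spearman_vector
from .datatypes import ExpressionMatrix

__all__ = [
    "normalize_expression",
    "filter_reliable_genes",
    "gene_density_profile",
    "category_scores",
]


def normalize_expression(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scaled robust sigmoid normalization of each gene across regions.

    Per gene: ``1 / (1 + exp(-(x - median) / (IQR / 1.349)))`` followed
    by a min-max rescale to [0, 1]; the SD replaces a zero IQR, and
    all-constant genes are dropped with a warning.  Region ranking
    within each gene is preserved exactly.
    """
    if matrix.values.shape[1] < 3:
        raise ValueError("need at least 3 regions per gene")
    scaled, dropped = robust_sigmoid_columns(matrix.values.values.T)
    if dropped.any():
        warnings.warn(
            f"dropping {int(dropped.sum())} constant gene(s)", stacklevel=2
        )
    keep = matrix.values.index[~dropped]
    vals = pd.DataFrame(
        scaled.T[~dropped], index=keep, columns=matrix.values.columns
    )
    return ExpressionMatrix(values=vals, source=matrix.source, normalized=True)


def filter_reliable_genes(
    sagittal: ExpressionMatrix,
    coronal: ExpressionMatrix,
    r_min: float = 0.70,
) -> list[str]:
    """Genes measured in both sources whose cross-source Spearman
    correlation over regions is >= ``r_min``.

    Downstream univariate analyses conventionally use the coronal
    values of the returned genes.
    """
    shared = sagittal.values.index.intersection(coronal.values.index)
    if len(shared) == 0:
        warnings.warn("no genes shared between sources", stacklevel=2)
        return []
    regions = sagittal.values.columns.intersection(coronal.values.columns)
    a = sagittal.values.loc[shared, regions].values
    b = coronal.values.loc[shared, regions].values
    ra = np.apply_along_axis(stats.rankdata, 1, a)
    rb = np.apply_along_axis(stats.rankdata, 1, b)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    denom = np.sqrt((ra**2).sum(axis=1) * (rb**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ra * rb).sum(axis=1) / denom
    return [g for g, ri in zip(shared, r) if np.isfinite(ri) and ri >= r_min]


def gene_density_profile(
    expression: ExpressionMatrix, density_map: pd.Series
) -> pd.Series:
    """Spearman r of every gene's spatial expression against a density map.

    Constant genes yield NaN (flagged missing).
    """
    regions = expression.values.columns.intersection(density_map.dropna().index)
    if len(regions) < 3:
        raise ValueError("need at least 3 matched regions")
    r = spearman_vector(
        density_map.loc[regions].values, expression.values[regions].values.T
    )
    return pd.Series(r, index=expression.values.index, name="r")


def category_scores(
    r_vector: pd.Series,
    annotation: dict[str, list[str]],
    min_size: int = 100,
    top: int | None = None,
) -> pd.DataFrame:
    """Rank gene categories by median |r| of their member genes.

    Only categories with at least ``min_size`` annotated genes having a
    finite r value qualify (genes annotated but absent from the
    expression set are ignored).  Returns a table sorted by descending
    score; ``top`` truncates it.
    """
    r = r_vector.dropna()
    rows = []
    for cat, genes in annotation.items():
        present = r.index.intersection(pd.Index(genes))
        if len(present) < min_size:
            continue
        rows.append((cat, float(r.loc[present].abs().median()), len(present)))
    table = (
        pd.DataFrame(rows, columns=["category", "score", "n_genes"])
        .sort_values("score", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    if top is not None:
        table = table.head(top)
    return table
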