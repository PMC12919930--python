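"""Inter-subject reliability of feature maps and sample-size extrapolation.

Pairwise spatial correlations of every feature across subject pairs,
individual-vs-group phenotype correlations, and the subgroup analysis:
average feature maps within every pair of disjoint size-N subgroups,
correlate across subgroups, and fit r̄(N) = a + b·ln N to extrapolate
reproducibility to larger samples.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import spearman
from .datatypes import FeatureMatrix

__all__ = [
    "pairwise_reliability",
    "individual_vs_group",
    "subgroup_extrapolation",
    "n_subgroup_pairs",
]


def _aligned_values(matrices: list[FeatureMatrix]) -> np.ndarray:
    if len(matrices) < 2:
        raise ValueError("need at least 2 subjects")
    first = matrices[0]
    for m in matrices[1:]:
        if not m.values.index.equals(first.values.index) or not m.values.columns.equals(
            first.values.columns
        ):
            raise ValueError("matrices must share regions and features")
    return np.stack([m.values.values for m in matrices])  # subjects x regions x feats


def _columnwise_spearman(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Spearman per column between two regions x features arrays."""
    ra = np.apply_along_axis(stats.rankdata, 0, A)
    rb = np.apply_along_axis(stats.rankdata, 0, B)
    ra = ra - ra.mean(axis=0)
    rb = rb - rb.mean(axis=0)
    denom = np.sqrt((ra**2).sum(axis=0) * (rb**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (ra * rb).sum(axis=0) / denom


def pairwise_reliability(matrices: list[FeatureMatrix]) -> dict:
    """Spearman r over regions for every (feature, subject pair).

    Constant feature columns make a pair undefined for that feature
    (skipped via NaN).  Returns the pair x feature table and the grand
    mean.
    """
    vals = _aligned_values(matrices)
    n_s = vals.shape[0]
    feats = matrices[0].values.columns
    rows, labels = [], []
    for i, j in combinations(range(n_s), 2):
        rows.append(_columnwise_spearman(vals[i], vals[j]))
        labels.append((i, j))
    table = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(labels), columns=feats)
    return {"pairwise": table, "grand_mean": float(np.nanmean(table.values))}


def individual_vs_group(
    matrices: list[FeatureMatrix], leave_one_out: bool = False
) -> dict:
    """Correlate each subject's phenotypes with the group mean.

    Region-wise: each subject's feature vector (across features) at a
    region vs the group-mean vector at that region.  Feature-wise: each
    subject's spatial map vs the group-mean map.  The group mean
    includes the subject itself unless ``leave_one_out`` is set.
    """
    vals = _aligned_values(matrices)
    n_s = vals.shape[0]
    regions = matrices[0].values.index
    feats = matrices[0].values.columns
    region_r = np.empty((n_s, len(regions)))
    feature_r = np.empty((n_s, len(feats)))
    total = np.nansum(vals, axis=0)
    for s in range(n_s):
        if leave_one_out:
            group = (total - np.nan_to_num(vals[s])) / (n_s - 1)
        else:
            group = total / n_s
        region_r[s] = _columnwise_spearman(vals[s].T, group.T)
        feature_r[s] = _columnwise_spearman(vals[s], group)
    return {
        "region_wise": pd.DataFrame(region_r, columns=regions),
        "feature_wise": pd.DataFrame(feature_r, columns=feats),
        "mean_region_r": float(np.nanmean(region_r)),
        "mean_feature_r": float(np.nanmean(feature_r)),
    }


def n_subgroup_pairs(n_subjects: int, n: int) -> int:
    """Closed-form count of unordered disjoint size-n subgroup pairs."""
    return comb(n_subjects, n) * comb(n_subjects - n, n) // 2


def subgroup_extrapolation(
    matrices: list[FeatureMatrix],
    n_values: tuple[int, ...] = (2, 3, 4, 5),
    n_target: int = 10,
) -> dict:
    """Reproducibility of group-mean feature maps vs subgroup size.

    For each N: enumerate every unordered pair of disjoint size-N
    subgroups, average feature maps within each subgroup, correlate the
    two means per feature (Spearman over regions), and average over
    features and pairs.  A logarithmic law r̄(N) = a + b·ln N is fit by
    unweighted least squares and evaluated at ``n_target``.
    """
    vals = _aligned_values(matrices)
    n_s = vals.shape[0]
    if len(set(n_values)) < 2:
        raise ValueError("need at least 2 distinct subgroup sizes")
    if 2 * max(n_values) > n_s:
        raise ValueError("subject count cannot host two disjoint subgroups")
    curve = {}
    counts = {}
    for n in n_values:
        rs = []
        n_pairs = 0
        for A in combinations(range(n_s), n):
            rest = [i for i in range(n_s) if i not in A]
            for B in combinations(rest, n):
                if B < A:  # each unordered pair once
                    continue
                n_pairs += 1
                ma = vals[list(A)].mean(axis=0)
                mb = vals[list(B)].mean(axis=0)
                rs.append(np.nanmean(_columnwise_spearman(ma, mb)))
        curve[n] = float(np.mean(rs))
        counts[n] = n_pairs
    ns = np.array(sorted(curve))
    rbar = np.array([curve[n] for n in ns])
    fit = fit_log_curve(ns, rbar, n_target)
    return {
        "curve": pd.Series(curve, name="mean_reproducibility"),
        "pair_counts": counts,
        **fit,
    }


def fit_log_curve(ns: np.ndarray, rbar: np.ndarray, n_target: int = 10) -> dict:
    """Unweighted least-squares fit of r̄(N) = a + b·ln N with its R² and
    the predicted reproducibility at ``n_target``."""
    ns = np.asarray(ns, dtype=float)
    rbar = np.asarray(rbar, dtype=float)
    if len(np.unique(ns)) < 2:
        raise ValueError("need at least 2 distinct subgroup sizes to fit")
    X = np.column_stack([np.ones(len(ns)), np.log(ns)])
    (a, b), *_ = np.linalg.lstsq(X, rbar, rcond=None)
    fitted = X @ np.array([a, b])
    sst = ((rbar - rbar.mean()) ** 2).sum()
    r2 = 1.0 - ((rbar - fitted) ** 2).sum() / sst if sst > 0 else 1.0
    return {
        "a": float(a),
        "b": float(b),
        "fit_r2": float(r2),
        "predicted": float(a + b * np.log(n_target)),
        "n_target": n_target,
    }
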