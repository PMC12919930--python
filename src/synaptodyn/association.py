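"""Mass-univariate density-feature mapping and sensitivity checks.

Each regional density map is correlated (Spearman) with every
time-series feature; Bonferroni correction is applied over the feature
count tested for that map.  Significant features are clustered
(agglomerative, average linkage on 1 - r) to pick a representative,
and confound analyses (SNR regression, motion-amplitude correlation,
global signal regression, cell-type specificity) probe robustness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering

from ._stats import bonferroni, spearman
from .datatypes import FeatureMatrix, TimeSeriesStack

__all__ = [
    "associate",
    "cluster_significant_features",
    "FeatureClusterResult",
    "residualize_confound",
    "motion_amplitude_check",
    "apply_gsr",
    "celltype_specificity",
]


def associate(
    density_map: pd.Series,
    features: FeatureMatrix,
    alpha: float = 0.05,
    r_min: float | None = None,
) -> pd.DataFrame:
    """Spearman r of a density map against every feature, Bonferroni-corrected.

    The Bonferroni family is the number of features tested for this map.
    ``r_min`` applies an optional secondary magnitude filter on the
    significance flag (used when a very large significant set needs
    thinning).  Returns a table (feature, r, p_raw, p_bonf, significant).
    """
    common = density_map.dropna().index.intersection(features.values.index)
    if len(common) < 5:
        raise ValueError("need at least 5 matched regions")
    dm = density_map.loc[common].values
    rows = []
    for feat in features.values.columns:
        r, p = spearman(dm, features.values.loc[common, feat].values)
        rows.append((feat, r, p))
    table = pd.DataFrame(rows, columns=["feature", "r", "p_raw"]).set_index("feature")
    m = int(table["p_raw"].notna().sum())
    table["p_bonf"] = bonferroni(table["p_raw"].values, m)
    table["significant"] = table["p_bonf"] < alpha
    if r_min is not None:
        table["significant"] &= table["r"].abs() > r_min
    return table


@dataclass
class FeatureClusterResult:
    """Chosen clustering of significant features and the representative."""

    chosen_k: int
    labels: pd.Series
    representative: str
    representative_family: str | None
    diagnostics: pd.DataFrame


def _cluster_score(
    sim: np.ndarray, labels: np.ndarray, small_size: int, penalty: float
) -> tuple[float, float, float, int]:
    n = len(labels)
    same = labels[:, None] == labels[None, :]
    off = ~np.eye(n, dtype=bool)
    within = sim[same & off]
    between = sim[~same]
    mean_w = within.mean() if within.size else 1.0
    mean_b = between.mean() if between.size else 0.0
    n_small = sum(
        1 for lab in np.unique(labels) if (labels == lab).sum() < small_size
    )
    return mean_w - mean_b - penalty * n_small, mean_w, mean_b, n_small


def cluster_significant_features(
    features: FeatureMatrix,
    r_vector: pd.Series,
    k_range: tuple[int, int] = (2, 10),
    small_size: int = 5,
    small_penalty: float = 0.05,
    representative: str | None = None,
) -> FeatureClusterResult:
    """Cluster the significant-feature similarity matrix and pick a
    representative.

    The feature x feature Spearman similarity is clustered with average
    linkage on distance 1 - r for k in ``k_range``; the chosen k
    maximizes (mean within-cluster r - mean between-cluster r), with a
    penalty per cluster smaller than ``small_size``.  The default
    representative is the feature with the largest |r| against the
    density map inside the largest cluster; an explicit choice (the
    irreducibly manual "explainability" criterion) overrides it.
    """
    cols = list(features.values.columns)
    if len(cols) == 0:
        raise ValueError("no features to cluster")
    fam = features.catalog["family"] if "family" in features.catalog.columns else None
    if len(cols) == 1:
        rep = cols[0]
        return FeatureClusterResult(
            chosen_k=1,
            labels=pd.Series([0], index=cols),
            representative=rep,
            representative_family=None if fam is None else fam.get(rep),
            diagnostics=pd.DataFrame(),
        )
    X = features.values[cols].values
    sim = np.array(
        [[spearman(X[:, i], X[:, j])[0] for j in range(len(cols))] for i in range(len(cols))]
    )
    np.fill_diagonal(sim, 1.0)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    lo, hi = k_range
    hi = min(hi, len(cols))
    lo = min(lo, hi)
    diag_rows = []
    best = None
    for k in range(lo, hi + 1):
        model = AgglomerativeClustering(
            n_clusters=k, metric="precomputed", linkage="average"
        )
        labels = model.fit_predict(dist)
        score, mean_w, mean_b, n_small = _cluster_score(
            sim, labels, small_size, small_penalty
        )
        sizes = np.bincount(labels)
        diag_rows.append((k, score, mean_w, mean_b, n_small, sizes.min()))
        if best is None or score > best[0]:
            best = (score, k, labels)
    _, chosen_k, labels = best
    labels = pd.Series(labels, index=cols, name="cluster")
    if representative is None:
        largest = labels.value_counts().idxmax()
        members = labels.index[labels == largest]
        representative = r_vector.loc[members].abs().idxmax()
    diagnostics = pd.DataFrame(
        diag_rows,
        columns=["k", "score", "mean_within_r", "mean_between_r", "n_small", "min_size"],
    ).set_index("k")
    return FeatureClusterResult(
        chosen_k=chosen_k,
        labels=labels,
        representative=representative,
        representative_family=None if fam is None else fam.get(representative),
        diagnostics=diagnostics,
    )


def residualize_confound(
    features: FeatureMatrix, confound: pd.Series, alpha: float = 0.05
) -> tuple[FeatureMatrix, int]:
    """Regress a regional confound map out of confound-associated features.

    Features whose Spearman association with the confound survives
    Bonferroni correction are replaced by residuals of a simple linear
    regression on the confound; all others are untouched.  A constant
    confound residualizes nothing.  Returns the new matrix and the
    count of residualized features.
    """
    common = confound.dropna().index.intersection(features.values.index)
    vals = features.values.copy()
    c = confound.loc[common].values
    if np.std(c) == 0:
        return FeatureMatrix(vals, features.catalog, features.normalized), 0
    assoc = associate(confound, features, alpha=alpha)
    n_res = 0
    Xc = np.column_stack([np.ones(len(common)), c])
    for feat in vals.columns:
        if not assoc.loc[feat, "significant"]:
            continue
        y = vals.loc[common, feat].values
        ok = np.isfinite(y)
        beta, _, _, _ = np.linalg.lstsq(Xc[ok], y[ok], rcond=None)
        resid = y - Xc @ beta
        vals.loc[common, feat] = resid
        n_res += 1
    return FeatureMatrix(vals, features.catalog, normalized=False), n_res


def motion_amplitude_check(stack: TimeSeriesStack) -> dict:
    """Correlate each regional signal with the frame-wise displacement trace.

    FD has length T-1; the signal is aligned by dropping its first time
    point.  Returns per-(subject, region) Pearson r, the median and
    range, and — when a density map is supplied downstream — the
    region-averaged r map for confound correlation.
    """
    if stack.motion is None:
        raise ValueError("stack has no motion traces")
    n_s, n_r, T = stack.values.shape
    r = np.empty((n_s, n_r))
    for s in range(n_s):
        fd = stack.motion[s]
        fdc = fd - fd.mean()
        fdn = np.sqrt((fdc**2).sum())
        for reg in range(n_r):
            y = stack.values[s, reg, 1:]
            yc = y - y.mean()
            denom = fdn * np.sqrt((yc**2).sum())
            r[s, reg] = (fdc * yc).sum() / denom if denom > 0 else np.nan
    table = pd.DataFrame(r, index=list(stack.subject_ids), columns=list(stack.region_ids))
    return {
        "per_subject_region": table,
        "median": float(np.nanmedian(r)),
        "range": (float(np.nanmin(r)), float(np.nanmax(r))),
        "region_mean": table.mean(axis=0),
    }


def apply_gsr(stack: TimeSeriesStack) -> TimeSeriesStack:
    """Global signal regression: per subject, the mean signal across
    regions is regressed out of each regional series and residuals are
    re-standardized (left as-is when a residual is near-constant, so
    downstream features flag it as degenerate)."""
    out = np.empty_like(stack.values)
    for s in range(stack.values.shape[0]):
        X = stack.values[s]
        g = X.mean(axis=0)
        gc = g - g.mean()
        denom = (gc**2).sum()
        for r in range(X.shape[0]):
            y = X[r]
            beta = (gc * (y - y.mean())).sum() / denom if denom > 0 else 0.0
            resid = y - y.mean() - beta * gc
            sdr = resid.std(ddof=1)
            out[s, r] = resid / sdr if sdr > 1e-10 else resid
    return TimeSeriesStack(
        values=out,
        region_ids=list(stack.region_ids),
        subject_ids=list(stack.subject_ids),
        state=list(stack.state),
        motion=stack.motion,
        snr=stack.snr,
    )


def celltype_specificity(
    density_maps: pd.DataFrame,
    cell_maps: pd.DataFrame,
    alpha: float = 0.05,
    features: FeatureMatrix | None = None,
) -> dict:
    """Spearman association of each synapse-type map with each cell-type
    density map, Bonferroni-corrected over the cell types per synapse
    type.  Optionally also counts, per cell map, the features it is
    significantly associated with (companion specificity check)."""
    common = density_maps.columns.intersection(cell_maps.columns)
    m = cell_maps.shape[0]
    rows = []
    for stype in density_maps.index:
        for ctype in cell_maps.index:
            r, p = spearman(
                density_maps.loc[stype, common].values,
                cell_maps.loc[ctype, common].values,
            )
            p_b = min(p * m, 1.0) if np.isfinite(p) else np.nan
            rows.append((stype, ctype, r, p, p_b, bool(p_b < alpha)))
    table = pd.DataFrame(
        rows,
        columns=["synapse_type", "cell_type", "r", "p_raw", "p_bonf", "significant"],
    )
    out = {"table": table}
    if features is not None:
        counts = {}
        for ctype in cell_maps.index:
            assoc = associate(cell_maps.loc[ctype, common], features, alpha=alpha)
            counts[ctype] = int(assoc["significant"].sum())
        out["feature_counts"] = pd.Series(counts, name="n_significant_features")
    return out
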