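"""Structure-function coupling via communicability.

A region's functional-connectivity profile is regressed on its
communicability profile (adjusted R^2 = baseline coupling); adding the
target region's synapse density as a second regressor gives the
augmented fit, and the per-region gain ΔR²adj quantifies how much the
density map explains function beyond structure.  Paired awake vs
anaesthetized ΔR²adj distributions are compared with a two-sided
Wilcoxon signed-rank test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import expm

from ._stats import adjusted_r2, ols_r2
from .datatypes import CouplingResult, FunctionalConnectome, StructuralConnectome

__all__ = [
    "communicability",
    "regional_coupling",
    "augmented_coupling",
    "compare_states",
]


def communicability(sc: StructuralConnectome, eps: float = 1e-12) -> np.ndarray:
    """Weighted communicability: exp(S^{-1/2} A S^{-1/2}).

    S is the diagonal of regional strengths s_i = (in-strength +
    out-strength) / 2, floored at ``eps``; the normalization reduces to
    the usual row-strength convention on undirected graphs.  Entry
    (i, j) is the inverse-factorial-weighted sum over all walks from i
    to j, a model of diffusive communication.
    """
    A = sc.weights
    if (A < 0).any():
        raise ValueError("communicability requires nonnegative weights")
    s = (A.sum(axis=0) + A.sum(axis=1)) / 2
    d = 1.0 / np.sqrt(np.maximum(s, eps))
    M = d[:, None] * A * d[None, :]
    return expm(M)


def _profiles(
    G: np.ndarray, F: np.ndarray, region_idx: int, subset: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    others = subset[subset != region_idx]
    return F[region_idx, others], G[region_idx, others], others


def regional_coupling(
    G: np.ndarray,
    fc: FunctionalConnectome,
    regions: list | None = None,
) -> pd.Series:
    """Baseline coupling: adjusted R^2 of FC profile ~ communicability
    profile, per region.  Regions with a zero-variance predictor are
    flagged missing (NaN)."""
    idx, subset = _subset_indices(fc, regions)
    if len(subset) < 5:
        raise ValueError("need at least 5 regions")
    out = {}
    for i in subset:
        y, x, _ = _profiles(G, fc.values, i, subset)
        if np.std(x) == 0 or np.std(y) == 0:
            out[fc.region_ids[i]] = np.nan
            continue
        r2 = ols_r2(y, x[:, None])
        out[fc.region_ids[i]] = adjusted_r2(r2, n=len(y), p=1)
    return pd.Series(out, name="r2_base")


def _subset_indices(fc: FunctionalConnectome, regions) -> tuple[dict, np.ndarray]:
    index = {r: i for i, r in enumerate(fc.region_ids)}
    if regions is None:
        subset = np.arange(len(fc.region_ids))
    else:
        missing = [r for r in regions if r not in index]
        if missing:
            raise ValueError(f"regions absent from FC: {missing[:5]}")
        subset = np.array([index[r] for r in regions])
    return index, subset


def augmented_coupling(
    G: np.ndarray,
    fc: FunctionalConnectome,
    density_maps: pd.DataFrame | pd.Series,
    regions: list | None = None,
) -> CouplingResult:
    """Coupling with synapse-density regressors.

    ``density_maps`` is one regional map (Series) or several (DataFrame,
    map x region); for target region j the regressors are the density
    values at j, which vary over the observations of region i's profile.
    Collinear density regressors are flagged but the fit (via
    least-squares pseudoinverse) still yields a delta.
    """
    if isinstance(density_maps, pd.Series):
        density_maps = density_maps.to_frame().T
    _, subset = _subset_indices(fc, regions)
    if len(subset) < 5:
        raise ValueError("need at least 5 regions")
    dvals = density_maps[ [fc.region_ids[i] for i in subset] ].values  # maps x subset
    pos_of = {i: k for k, i in enumerate(subset)}
    p_aug = 1 + dvals.shape[0]
    rows = []
    for i in subset:
        y, x, others = _profiles(G, fc.values, i, subset)
        name = fc.region_ids[i]
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append((name, np.nan, np.nan, np.nan, True))
            continue
        D = dvals[:, [pos_of[j] for j in others]].T
        X_aug = np.column_stack([x, D])
        r2_b = ols_r2(y, x[:, None])
        r2_a = ols_r2(y, X_aug)
        flagged = bool(np.linalg.matrix_rank(X_aug - X_aug.mean(axis=0)) < X_aug.shape[1])
        a_b = adjusted_r2(r2_b, n=len(y), p=1)
        a_a = adjusted_r2(r2_a, n=len(y), p=X_aug.shape[1])
        rows.append((name, a_b, a_a, a_a - a_b, flagged))
    table = pd.DataFrame(
        rows, columns=["region", "r2_base", "r2_aug", "delta", "flagged"]
    ).set_index("region")
    return CouplingResult(
        table=table,
        regressors=["communicability"] + list(density_maps.index),
        n_obs=len(subset) - 1,
        n_predictors_aug=p_aug,
    )


def compare_states(
    delta_a: pd.Series,
    delta_b: pd.Series,
    strata: pd.Series | None = None,
    zero_method: str = "wilcox",
) -> dict:
    """Two-sided Wilcoxon signed-rank test on paired regional deltas.

    Zero differences are discarded before ranking (classic Wilcoxon;
    ``zero_method='pratt'`` keeps them).  An optional per-region strata
    labelling adds a stratified breakdown.  All-zero differences are
    degenerate: p = 1 with a flag.
    """
    common = delta_a.dropna().index.intersection(delta_b.dropna().index)
    if len(common) < 6:
        raise ValueError("need at least 6 paired regions")
    a = delta_a.loc[common].values
    b = delta_b.loc[common].values
    diff = a - b
    result = {
        "n": int(len(common)),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "degenerate": False,
    }
    if np.all(diff == 0):
        result.update({"statistic": np.nan, "p": 1.0, "degenerate": True})
    else:
        st = stats.wilcoxon(a, b, zero_method=zero_method, alternative="two-sided")
        result.update({"statistic": float(st.statistic), "p": float(st.pvalue)})
    if strata is not None:
        breakdown = {}
        for label in pd.unique(strata.loc[common]):
            idx = [r for r in common if strata.loc[r] == label]
            if len(idx) < 6:
                breakdown[label] = {"n": len(idx), "p": np.nan}
                continue
            da, db = delta_a.loc[idx].values, delta_b.loc[idx].values
            if np.all(da - db == 0):
                breakdown[label] = {"n": len(idx), "p": 1.0}
            else:
                stt = stats.wilcoxon(da, db, zero_method=zero_method)
                breakdown[label] = {"n": len(idx), "p": float(stt.pvalue)}
        result["strata"] = breakdown
    return result
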