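"""Structural and functional connectome construction and the
degree-based density associations.

The structural connectome is built from a candidate edge list carrying
per-edge p-values from the underlying tract-tracing model; the filter
keeps significant edges (p < alpha).  Functional connectomes are
per-subject Pearson correlation matrices averaged across subjects
(arithmetic mean of r; a Fisher-z option is exposed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._stats import spearman
from .datatypes import (
    DensityMatrix,
    FunctionalConnectome,
    StructuralConnectome,
    TimeSeriesStack,
)

__all__ = [
    "build_structural_connectome",
    "build_functional_connectome",
    "degrees",
    "layer_degree_association",
    "lifetime_degree_relation",
]


def build_structural_connectome(
    edges: pd.DataFrame,
    region_ids: list | None = None,
    alpha: float = 0.05,
    keep_significant: bool = True,
) -> StructuralConnectome:
    """Assemble the weighted directed adjacency from a candidate edge list.

    ``edges`` needs columns (source, target, weight, p).  With
    ``keep_significant`` (default), edges with p < alpha are retained
    and the rest zeroed; the opposite polarity is available for
    sensitivity checks.  Self-loops and duplicate (source, target)
    rows are rejected.
    """
    required = {"source", "target", "weight", "p"}
    if not required.issubset(edges.columns):
        raise ValueError(f"edge list must have columns {sorted(required)}")
    if (edges["source"] == edges["target"]).any():
        raise ValueError("self-connections are not allowed")
    if edges.duplicated(subset=["source", "target"]).any():
        raise ValueError("duplicate (source, target) rows")
    if region_ids is None:
        region_ids = sorted(set(edges["source"]) | set(edges["target"]))
    index = {r: i for i, r in enumerate(region_ids)}
    n = len(region_ids)
    W = np.zeros((n, n))
    P = np.full((n, n), np.nan)
    sig = edges["p"] < alpha
    keep = sig if keep_significant else ~sig
    for _, row in edges.iterrows():
        i, j = index[row["source"]], index[row["target"]]
        P[i, j] = row["p"]
    for _, row in edges[keep].iterrows():
        i, j = index[row["source"]], index[row["target"]]
        W[i, j] = row["weight"]
    return StructuralConnectome(weights=W, pvalues=P, region_ids=list(region_ids))


def build_functional_connectome(
    stack: TimeSeriesStack, state: str | None = None, fisher_z: bool = False
) -> FunctionalConnectome:
    """Group-average functional connectivity.

    Per-subject Pearson correlation matrices over regional series,
    averaged across subjects (on r by default; on Fisher z when
    requested), with the diagonal zeroed.
    """
    sub = stack if state is None else stack.subset_state(state)
    mats = []
    for s in range(sub.values.shape[0]):
        X = sub.values[s]
        sds = X.std(axis=1, ddof=1)
        if (sds == 0).any():
            bad = [sub.region_ids[i] for i in np.where(sds == 0)[0]]
            raise ValueError(f"constant series in regions {bad}")
        C = np.corrcoef(X)
        if fisher_z:
            C = np.arctanh(np.clip(C, -1 + 1e-15, 1 - 1e-15))
        mats.append(C)
    M = np.mean(mats, axis=0)
    if fisher_z:
        M = np.tanh(M)
    M = (M + M.T) / 2
    np.fill_diagonal(M, 0.0)
    return FunctionalConnectome(
        values=M,
        region_ids=list(sub.region_ids),
        state=state or (sub.state[0] if sub.state else "awake"),
    )


def degrees(
    sc: StructuralConnectome, fc: FunctionalConnectome | None = None
) -> pd.DataFrame:
    """Weighted in-/out-strength of the structural connectome and the
    signed functional strength (plain sum of correlations)."""
    out = pd.DataFrame(index=pd.Index(sc.region_ids, name="region"))
    out["in_strength"] = sc.weights.sum(axis=0)
    out["out_strength"] = sc.weights.sum(axis=1)
    if fc is not None:
        if list(fc.region_ids) != list(sc.region_ids):
            raise ValueError("SC and FC region sets must match")
        out["fc_strength"] = fc.values.sum(axis=1)  # diag is zero
    return out


def layer_degree_association(
    layer_maps: pd.DataFrame, degree_table: pd.DataFrame, min_pairs: int = 5
) -> pd.DataFrame:
    """Spearman association of per-layer density maps with in-/out-strength.

    ``layer_maps`` is layer x region with NaN outside each layer's
    coverage; missing regions are handled pairwise-complete.  Cells
    with fewer than ``min_pairs`` complete pairs are flagged missing.
    """
    rows = []
    for layer in layer_maps.index:
        lm = layer_maps.loc[layer]
        for kind in ("in_strength", "out_strength"):
            deg = degree_table[kind]
            common = lm.dropna().index.intersection(deg.dropna().index)
            if len(common) < min_pairs:
                rows.append((layer, kind, np.nan, np.nan, len(common)))
                continue
            r, p = spearman(lm.loc[common].values, deg.loc[common].values)
            rows.append((layer, kind, r, p, len(common)))
    return pd.DataFrame(rows, columns=["layer", "degree", "r", "p", "n"])


def lifetime_degree_relation(
    density: DensityMatrix,
    degree_table: pd.DataFrame,
    method: str = "spearman",
) -> dict:
    """Do longer-lifetime subtypes sit on better-connected regions?

    Step 1: per PSD95 subtype, Spearman r of its density map against
    in- and out-strength.  Step 2: correlate those r values with the
    subtype lifetimes across subtypes (Spearman by default, Pearson
    available).  Subtypes without a lifetime are excluded; identical
    lifetimes make the step-2 correlation undefined (flagged NaN).
    """
    lt = density.subtype_meta["lifetime"].dropna()
    if len(lt) < 3:
        raise ValueError("need at least 3 subtypes with lifetime values")
    common = density.values.columns.intersection(degree_table.index)
    r_in, r_out = {}, {}
    for subtype in lt.index:
        dmap = density.values.loc[subtype, common].values
        r_in[subtype], _ = spearman(dmap, degree_table.loc[common, "in_strength"].values)
        r_out[subtype], _ = spearman(dmap, degree_table.loc[common, "out_strength"].values)
    step1 = pd.DataFrame({"r_in": r_in, "r_out": r_out, "lifetime": lt})
    if lt.nunique() < 2:
        return {"step1": step1, "r_in": np.nan, "r_out": np.nan, "degenerate": True}
    if method == "spearman":
        ri, _ = spearman(step1["lifetime"].values, step1["r_in"].values)
        ro, _ = spearman(step1["lifetime"].values, step1["r_out"].values)
    elif method == "pearson":
        ri = float(np.corrcoef(step1["lifetime"], step1["r_in"])[0, 1])
        ro = float(np.corrcoef(step1["lifetime"], step1["r_out"])[0, 1])
    else:
        raise ValueError("method must be 'spearman' or 'pearson'")
    return {"step1": step1, "r_in": ri, "r_out": ro, "degenerate": False}
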