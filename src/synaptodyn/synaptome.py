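"""Synapse-type discovery from subtype density maps.

Aggregates fine anatomical samples to a parent parcellation, computes
the subtype x subtype spatial-similarity (Spearman) matrix, clusters
subtypes into synapse types with a seeded consensus Louvain procedure
(stratified by scaffolding protein), and averages member subtypes into
named cluster-mean density maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from ._stats import spearman, spearman_vector
from .datatypes import DensityMatrix

__all__ = [
    "ConsensusParams",
    "aggregate_to_parcellation",
    "subtype_similarity",
    "consensus_cluster",
    "cluster_mean_maps",
    "hemispheric_symmetry",
]


@dataclass(frozen=True)
class ConsensusParams:
    """Consensus Louvain settings: resolution gamma, repetitions, seed."""

    gamma: float = 1.0
    reps: int = 250
    seed: int = 0
    tau: float = 0.5  # agreement threshold for the consensus iteration

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


def aggregate_to_parcellation(
    density: DensityMatrix, region_table: pd.DataFrame, target_col: str = "parent_id"
) -> DensityMatrix:
    """Average fine samples into their parent regions.

    ``region_table`` is indexed by the fine region ids of ``density``
    and carries a ``target_col`` column naming each sample's unique
    parent.  Parents with no children are simply absent from the output
    (never zero-filled).
    """
    cols = density.values.columns
    missing = cols.difference(region_table.index)
    if len(missing):
        raise ValueError(f"regions absent from region table: {list(missing)[:5]}")
    parents = region_table.loc[cols, target_col]
    if parents.isna().any():
        raise ValueError("every sample must map to a parent region")
    agg = density.values.T.groupby(parents.values).mean().T
    agg.columns.name = density.values.columns.name
    ontology = None
    if "ontology" in region_table.columns:
        ont = region_table.loc[cols].groupby(target_col)["ontology"].first()
        ontology = ont.loc[agg.columns]
    return DensityMatrix(
        values=agg, subtype_meta=density.subtype_meta, region_ontology=ontology
    )


def subtype_similarity(density: DensityMatrix) -> pd.DataFrame:
    """Pairwise Spearman correlation of subtype maps across regions.

    Constant subtype rows produce NaN rows/columns (undefined ranks);
    the diagonal is fixed at 1.
    """
    if density.values.shape[1] < 3:
        raise ValueError("need at least 3 regions")
    vals = density.values.values.T  # regions x subtypes
    n = vals.shape[1]
    sim = np.empty((n, n))
    for i in range(n):
        sim[:, i] = spearman_vector(vals[:, i], vals)
    sim = (sim + sim.T) / 2  # symmetrize away float noise
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=density.values.index, columns=density.values.index)


def _louvain_labels(
    W: np.ndarray, gamma: float, seed: int, nodes: list
) -> np.ndarray:
    G = nx.Graph()
    G.add_nodes_from(range(len(nodes)))
    n = len(nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if W[i, j] > 0:
                G.add_edge(i, j, weight=float(W[i, j]))
    comms = nx.community.louvain_communities(
        G, weight="weight", resolution=gamma, seed=seed
    )
    labels = np.empty(n, dtype=int)
    for c, members in enumerate(comms):
        for m in members:
            labels[m] = c
    return labels


def _consensus_on_matrix(
    sim: np.ndarray, params: ConsensusParams, seed_offset: int
) -> np.ndarray:
    """Agreement-matrix consensus iteration on one stratum."""
    n = sim.shape[0]
    if n == 1:
        return np.zeros(1, dtype=int)
    rng = np.random.default_rng(params.seed + seed_offset)
    W = np.clip(np.array(sim, dtype=float), 0, None)
    np.fill_diagonal(W, 0.0)
    for _ in range(100):
        runs = np.empty((params.reps, n), dtype=int)
        for r in range(params.reps):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            runs[r] = _louvain_labels(W, params.gamma, sub_seed, list(range(n)))
        agree = np.zeros((n, n))
        for r in range(params.reps):
            lab = runs[r]
            agree += (lab[:, None] == lab[None, :]).astype(float)
        agree /= params.reps
        np.fill_diagonal(agree, 0.0)
        # converged when every run produced the same partition
        first = runs[0]
        if all(
            np.array_equal(
                first[:, None] == first[None, :], runs[r][:, None] == runs[r][None, :]
            )
            for r in range(1, params.reps)
        ):
            return first
        W = np.where(agree >= params.tau, agree, 0.0)
    return runs[0]


def consensus_cluster(
    similarity: pd.DataFrame,
    params: ConsensusParams = ConsensusParams(),
    strata: pd.Series | None = None,
) -> pd.Series:
    """Consensus Louvain clustering of the subtype similarity matrix.

    Negative similarities are zeroed for the modularity computation.
    When ``strata`` (e.g. protein class per subtype) is given, each
    stratum is clustered independently and labels are made globally
    unique.  Deterministic for a fixed seed.
    """
    S = similarity.values
    if S.shape[0] != S.shape[1]:
        raise ValueError("similarity must be square")
    if not np.allclose(S, S.T, atol=1e-10, equal_nan=True):
        raise ValueError("similarity must be symmetric")
    labels = pd.Series(index=similarity.index, dtype=int, name="cluster")
    if strata is None:
        strata = pd.Series("all", index=similarity.index)
    offset = 0
    for k, stratum in enumerate(pd.unique(strata)):
        idx = strata.index[strata == stratum]
        pos = [similarity.index.get_loc(i) for i in idx]
        sub = S[np.ix_(pos, pos)]
        lab = _consensus_on_matrix(sub, params, seed_offset=1000 * k)
        labels.loc[idx] = lab + offset
        offset += lab.max() + 1
    return labels


def cluster_mean_maps(
    density: DensityMatrix,
    labels: pd.Series,
    drop_singletons: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average subtype maps within each cluster and name the maps.

    PSD95 clusters are named ``psd95_long`` / ``psd95_short`` by mean
    subtype lifetime (ties toward "long"); other clusters get
    ``<class>_<k>`` names (a lone SAP102 cluster is just ``sap102``).
    Naming follows cluster membership, not individual lifetimes; member
    subtypes whose own lifetime disagrees with their cluster's label
    are listed in the returned metadata.

    Returns (maps, meta): ``maps`` is map-name x region, ``meta`` has
    one row per retained cluster (label, protein class, members,
    mean lifetime, lifetime_outliers).
    """
    if not labels.index.equals(density.values.index):
        raise ValueError("labels must cover all subtypes")
    meta_rows = []
    maps = {}
    classes = density.subtype_meta["protein_class"]
    lifetimes = density.subtype_meta.get("lifetime")
    for cls in pd.unique(classes):
        cls_idx = classes.index[classes == cls]
        cls_labels = labels.loc[cls_idx]
        clusters = []
        for lab in sorted(cls_labels.unique()):
            members = cls_labels.index[cls_labels == lab]
            if drop_singletons and len(members) == 1:
                continue
            mean_map = density.values.loc[members].mean(axis=0)
            mean_lt = (
                float(lifetimes.loc[members].mean())
                if lifetimes is not None and lifetimes.loc[members].notna().any()
                else np.nan
            )
            clusters.append((lab, members, mean_map, mean_lt))
        if cls == "PSD95" and len(clusters) == 2 and all(
            np.isfinite(c[3]) for c in clusters
        ):
            order = sorted(clusters, key=lambda c: -c[3])  # ties keep first = long
            names = ["psd95_long", "psd95_short"]
        elif len(clusters) == 1:
            names = [cls.lower()]
            order = clusters
        else:
            order = clusters
            names = [f"{cls.lower()}_{i + 1}" for i in range(len(clusters))]
        for name, (lab, members, mean_map, mean_lt) in zip(names, order):
            maps[name] = mean_map
            outliers: list = []
            if lifetimes is not None and np.isfinite(mean_lt) and name.startswith("psd95"):
                grand = lifetimes.loc[classes == "PSD95"].mean()
                want_high = name == "psd95_long"
                for m in members:
                    lt = lifetimes.loc[m]
                    if np.isfinite(lt) and ((lt >= grand) != want_high):
                        outliers.append(m)
            meta_rows.append(
                {
                    "name": name,
                    "label": lab,
                    "protein_class": cls,
                    "n_members": len(members),
                    "members": list(members),
                    "mean_lifetime": mean_lt,
                    "lifetime_outliers": outliers,
                }
            )
    maps_df = pd.DataFrame(maps).T
    maps_df.columns = density.values.columns
    meta = pd.DataFrame(meta_rows).set_index("name")
    return maps_df, meta


def hemispheric_symmetry(
    density_left: DensityMatrix, density_right: DensityMatrix
) -> pd.Series:
    """Spearman r between hemispheres, per subtype, over matched regions."""
    if not density_left.values.columns.equals(density_right.values.columns):
        raise ValueError("hemisphere region sets must match")
    if not density_left.values.index.equals(density_right.values.index):
        raise ValueError("subtype sets must match")
    out = {}
    for subtype in density_left.values.index:
        r, _ = spearman(
            density_left.values.loc[subtype].values,
            density_right.values.loc[subtype].values,
        )
        out[subtype] = r
    return pd.Series(out, name="hemispheric_r")
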