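"""Synthetic multiscale data with planted ground truth.

Every pipeline input — subtype density maps, regional BOLD-like
time-series, structural and functional connectomes, gene expression —
is generated from known latent structure so that each downstream stage
has a parameter-recovery test.  The mechanisms are stand-ins chosen for
testability, not claims about biology.

Latent spatial maps are smooth low-rank gradients (a few sinusoidal
components over the region axis plus ontology-block offsets) rather
than i.i.d. noise, mimicking the spatial autocorrelation of real brain
maps.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy.stats import rankdata

from .config import GroundTruth, SynthConfig
from .coupling import communicability
from .datatypes import (
    DensityMatrix,
    ExpressionMatrix,
    FunctionalConnectome,
    StructuralConnectome,
    TimeSeriesStack,
)
from .network import build_structural_connectome

__all__ = [
    "gen_density",
    "gen_timeseries",
    "gen_connectomes",
    "gen_edge_candidates",
    "gen_expression",
    "gen_parcellation_hierarchy",
    "region_ontology_labels",
]

ONTOLOGY_WEIGHTS = {
    "isocortex": 0.30,
    "olfactory": 0.09,
    "cortical subplate": 0.07,
    "hippocampus": 0.09,
    "thalamus": 0.13,
    "hypothalamus": 0.09,
    "midbrain": 0.09,
    "pons": 0.07,
    "medulla": 0.07,
}


def region_ontology_labels(n_regions: int) -> pd.Series:
    """Assign major-structure ontology labels to ``n_regions`` regions,
    proportionally to a fixed anatomical weighting."""
    labels = []
    names = list(ONTOLOGY_WEIGHTS)
    counts = np.floor(np.array(list(ONTOLOGY_WEIGHTS.values())) * n_regions).astype(int)
    counts[0] += n_regions - counts.sum()  # remainder into the largest stratum
    for name, c in zip(names, counts):
        labels += [name] * c
    ids = [f"R{i:03d}" for i in range(n_regions)]
    return pd.Series(labels, index=ids, name="ontology")


def _smooth_map(rng: np.random.Generator, n: int, ontology: pd.Series) -> np.ndarray:
    """A smooth low-rank spatial gradient: sinusoids + ontology offsets."""
    u = np.arange(n) / n
    x = np.zeros(n)
    for k in range(1, 5):
        x += rng.normal() / k * np.sin(2 * np.pi * k * u + rng.uniform(0, 2 * np.pi))
    codes = pd.Categorical(ontology).codes
    offsets = rng.normal(scale=0.6, size=codes.max() + 1)
    x = x + offsets[codes]
    return (x - x.mean()) / x.std(ddof=1)


def _rank_unit(x: np.ndarray) -> np.ndarray:
    """Rank-normalize a map to [0, 1]."""
    r = rankdata(x)
    return (r - 1) / (len(r) - 1)


def gen_density(config: SynthConfig) -> tuple[DensityMatrix, GroundTruth]:
    """Generate the subtype x region density matrix with planted clusters.

    Subtypes within a planted cluster are noisy monotone (exponential)
    transforms of one shared latent map.  PSD95 subtypes split into a
    high-lifetime and a low-lifetime cluster; colocalized subtypes
    follow either the SAP102 or the long-lifetime PSD95 latent, plus
    one singleton with its own latent.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_regions
    ontology = region_ontology_labels(n)
    regions = list(ontology.index)

    # orthogonalized smooth gradients: mutually uncorrelated planted maps,
    # so one mechanism's recovery cannot leak into another's
    raw = np.column_stack([_smooth_map(rng, n, ontology) for _ in range(4)])
    q, _ = np.linalg.qr(raw - raw.mean(axis=0))
    q = (q - q.mean(axis=0)) / q.std(axis=0, ddof=1)
    # the singleton's map anti-correlates with the big coloc clusters so it
    # stays isolated (its similarities clip to zero under the Louvain step)
    singleton = -(q[:, 0] + q[:, 2]) / np.sqrt(2) + 0.3 * q[:, 3]
    singleton = (singleton - singleton.mean()) / singleton.std(ddof=1)
    latents = {
        "psd95_long": q[:, 0],
        "psd95_short": q[:, 1],
        "sap102": q[:, 2],
        "coloc_singleton": singleton,
    }

    n_long = int(np.ceil(config.n_subtypes_psd95 * 6 / 11))
    n_short = config.n_subtypes_psd95 - n_long
    n_coloc_sap = (config.n_subtypes_coloc - 1) // 2
    n_coloc_psd = config.n_subtypes_coloc - 1 - n_coloc_sap

    plan: list[tuple[str, str, str]] = []  # (subtype id, class, cluster)
    for i in range(n_long):
        plan.append((f"PSD95_{i + 1:02d}", "PSD95", "psd95_long"))
    for i in range(n_short):
        plan.append((f"PSD95_{n_long + i + 1:02d}", "PSD95", "psd95_short"))
    for i in range(config.n_subtypes_sap102):
        plan.append((f"SAP102_{i + 1:02d}", "SAP102", "sap102"))
    for i in range(n_coloc_sap):
        plan.append((f"COLOC_{i + 1:02d}", "coloc", "coloc_sap102like"))
    for i in range(n_coloc_psd):
        plan.append((f"COLOC_{n_coloc_sap + i + 1:02d}", "coloc", "coloc_psd95like"))
    plan.append((f"COLOC_{config.n_subtypes_coloc:02d}", "coloc", "coloc_singleton"))

    cluster_latent = {
        "psd95_long": latents["psd95_long"],
        "psd95_short": latents["psd95_short"],
        "sap102": latents["sap102"],
        "coloc_sap102like": latents["sap102"],
        "coloc_psd95like": latents["psd95_long"],
        "coloc_singleton": latents["coloc_singleton"],
    }

    rows = []
    lifetimes = {}
    for subtype, cls, cluster in plan:
        latent = cluster_latent[cluster]
        noisy = latent + config.density_noise * rng.normal(size=n)
        amp = np.exp(rng.normal(scale=0.2))
        rows.append(amp * np.exp(0.6 * noisy))
        if cls == "PSD95":
            if cluster == "psd95_long":
                lifetimes[subtype] = float(rng.uniform(65, 90))
            else:
                lifetimes[subtype] = float(rng.uniform(20, 45))
        else:
            lifetimes[subtype] = np.nan

    subtypes = [p[0] for p in plan]
    values = pd.DataFrame(rows, index=pd.Index(subtypes, name="subtype"), columns=regions)
    meta = pd.DataFrame(
        {
            "protein_class": [p[1] for p in plan],
            "lifetime": [lifetimes[s] for s in subtypes],
            "planted_cluster": [p[2] for p in plan],
        },
        index=values.index,
    )
    truth = GroundTruth(
        planted_cluster_of_subtype=meta["planted_cluster"].copy(),
        planted_maps=pd.DataFrame(latents, index=regions).T,
        lifetimes=pd.Series(lifetimes, name="lifetime"),
        true_effects={
            "effect_statav": config.effect_statav,
            "effect_outlier": config.effect_outlier,
            "state_effect": config.state_effect,
        },
    )
    return DensityMatrix(values=values, subtype_meta=meta, region_ontology=ontology), truth


def _derived_maps(density: DensityMatrix) -> pd.DataFrame:
    """Cluster-mean maps implied by the generator's planted labels
    (falling back to a lifetime split when labels are absent)."""
    meta = density.subtype_meta
    if "planted_cluster" in meta.columns:
        groups = meta["planted_cluster"]
    else:
        cls = meta["protein_class"]
        lt = meta["lifetime"]
        groups = pd.Series("other", index=meta.index)
        psd = cls == "PSD95"
        groups[psd & (lt >= lt[psd].mean())] = "psd95_long"
        groups[psd & (lt < lt[psd].mean())] = "psd95_short"
        groups[cls == "SAP102"] = "sap102"
    return density.values.groupby(groups.values).mean()


def gen_timeseries(
    config: SynthConfig, density: DensityMatrix, state: str = "awake"
) -> tuple[TimeSeriesStack, dict]:
    """Generate standardized regional signals whose nonstationarity and
    negative-outlier timing covary with the planted density maps.

    Mechanism per region r (maps rank-normalized to [0, 1], jittered by
    ``map_jitter`` once per dataset):

    * base AR(1) noise with a per-region coefficient drawn independently
      of all planted maps (so autocorrelation features do not track the
      planted mechanisms);
    * per-segment mean offsets with SD = statav_base +
      effect_statav * u_long(r)  (drives StatAv);
    * injected negative spikes whose times follow Beta(a, 1) with
      a = 1 + effect_outlier * u_sap(r)  (larger -> later events);
    * an independent per-subject motion trace and a regional SNR map.

    Each series is z-scored (sample SD).  Returns the stack and a dict
    with the effective per-region mechanism maps for recovery tests.
    """
    if len(density.values.columns) != config.n_regions:
        raise ValueError("density regions do not match config")
    T = config.n_timepoints
    if T < 20 * config.n_segments:
        raise ValueError("time-series too short for the segment structure")
    rng = np.random.default_rng(config.seed + 1)
    n_r, n_s = config.n_regions, config.n_subjects

    maps = _derived_maps(density)
    u_long = _rank_unit(maps.loc["psd95_long"].values)
    u_sap = _rank_unit(maps.loc["sap102"].values)

    jit1 = rng.normal(scale=config.map_jitter, size=n_r)
    jit2 = rng.normal(scale=config.map_jitter, size=n_r)
    drive_statav = np.clip(u_long + jit1, 0, None)
    drive_outlier = np.clip(u_sap + jit2, 0, None)
    sigma_seg = config.statav_base + config.effect_statav * drive_statav
    beta_a = 1.0 + config.effect_outlier * drive_outlier

    phi = rng.uniform(config.ar_phi_low, config.ar_phi_high, size=n_r)
    # per-region white observation noise, independent of all planted maps:
    # together with the AR(1) jitter it gives scaling/autocorrelation
    # features map-independent variance of their own
    obs_noise = rng.uniform(0.0, config.obs_noise_max, size=n_r)
    snr = pd.Series(
        _rank_unit(_smooth_map(rng, n_r, region_ontology_labels(n_r))),
        index=list(density.values.columns),
        name="snr",
    )
    noise_scale = 1.0 + config.snr_coupling * (0.5 - snr.values)

    innov = rng.normal(size=(n_s, n_r, T))
    x = np.empty_like(innov)
    for r in range(n_r):
        x[:, r, :] = sp_signal.lfilter([1.0], [1.0, -phi[r]], innov[:, r, :], axis=1)
        x[:, r, :] *= noise_scale[r]
    base_sd = noise_scale * np.sqrt(1.0 / (1 - phi**2) + obs_noise**2)
    x += (noise_scale[None, :] * obs_noise[None, :])[:, :, None] * rng.normal(
        size=(n_s, n_r, T)
    )
    # slow oscillation with map-independent per-region amplitude/period:
    # a second source of large-scale structure, so fluctuation-scaling
    # features have variance of their own beyond the planted drift
    osc_amp = rng.uniform(0.0, config.osc_max, size=n_r) * base_sd
    osc_period = rng.uniform(150, 600, size=n_r)
    tt = np.arange(T, dtype=float)
    for r in range(n_r):
        phase = rng.uniform(0, 2 * np.pi, size=n_s)
        x[:, r, :] += osc_amp[r] * np.sin(
            2 * np.pi * tt[None, :] / osc_period[r] + phase[:, None]
        )
    base_sd = np.sqrt(base_sd**2 + osc_amp**2 / 2)

    seg_len = T // config.n_segments
    offsets = rng.normal(size=(n_s, n_r, config.n_segments)) * sigma_seg[None, :, None]
    # zero-sum per series: the drift lives at the segment scale, not as a
    # whole-series trend (sample SD of the offsets is unchanged)
    offsets -= offsets.mean(axis=2, keepdims=True)
    seg_index = np.minimum(np.arange(T) // seg_len, config.n_segments - 1)
    x += offsets[:, :, seg_index]

    # spike depth tracks the full signal SD (drift included) so that the
    # post-standardization spike magnitude is uniform across regions
    total_sd = np.sqrt(base_sd**2 + sigma_seg**2)
    seg_counts = np.bincount(seg_index, minlength=config.n_segments)
    for s in range(n_s):
        for r in range(n_r):
            k = rng.poisson(config.event_rate)
            if k == 0:
                continue
            # events live in the last 90% of the recording; the map shifts
            # their timing within that span (keeps the initial window,
            # which local-variance features read, event-free everywhere)
            times = np.floor((0.1 + 0.9 * rng.beta(beta_a[r], 1.0, size=k)) * T).astype(int)
            times = np.clip(times, 0, T - 1)
            amps = -config.spike_amp * total_sd[r] * rng.uniform(0.8, 1.2, size=k)
            delta = np.zeros(T)
            np.add.at(delta, times, amps)
            # mean-neutral within each segment: event timing must not leak
            # into the segment-mean drift that StatAv measures
            seg_means = np.bincount(seg_index, weights=delta, minlength=config.n_segments) / seg_counts
            delta -= seg_means[seg_index]
            x[s, r] += delta

    motion = rng.lognormal(mean=-3.0, sigma=0.5, size=(n_s, T - 1))
    if config.motion_coupling != 0:
        m = (motion - motion.mean(axis=1, keepdims=True)) / motion.std(
            axis=1, ddof=1, keepdims=True
        )
        x[:, :, 1:] += config.motion_coupling * m[:, None, :]

    x -= x.mean(axis=2, keepdims=True)
    x /= x.std(axis=2, ddof=1, keepdims=True)

    stack = TimeSeriesStack(
        values=x,
        region_ids=list(density.values.columns),
        subject_ids=[f"{state}_{i + 1:02d}" for i in range(n_s)],
        state=[state] * n_s,
        motion=motion,
        snr=snr,
    )
    info = {
        "sigma_seg": sigma_seg,
        "beta_a": beta_a,
        "u_long": u_long,
        "u_sap": u_sap,
        "effects": {
            "effect_statav": config.effect_statav,
            "effect_outlier": config.effect_outlier,
        },
    }
    return stack, info


def gen_edge_candidates(config: SynthConfig, density: DensityMatrix) -> pd.DataFrame:
    """Candidate edge list: planted edges (small p) plus an equal number
    of spurious candidates (large p) for exercising the p-value filter."""
    rng = np.random.default_rng(config.seed + 2)
    n = config.n_regions
    maps = _derived_maps(density)
    u_long = _rank_unit(maps.loc["psd95_long"].values)
    h = u_long - 0.5  # hubness: long-lifetime-dense regions are hubs

    src, tgt = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    off = src != tgt
    src, tgt = src[off], tgt[off]
    score = h[src] + h[tgt] + rng.gumbel(scale=0.7, size=src.size)
    n_edges = int(round(config.sc_density * n * (n - 1)))
    order = np.argsort(-score)
    planted = order[:n_edges]
    spurious = order[n_edges : 2 * n_edges]

    regions = np.array(density.values.columns)
    rows = []
    w_pl = np.exp(rng.normal(size=n_edges) + 0.8 * (h[src[planted]] + h[tgt[planted]]))
    for k, e in enumerate(planted):
        rows.append(
            (regions[src[e]], regions[tgt[e]], w_pl[k], rng.uniform(0, 0.01))
        )
    w_sp = 0.1 * np.exp(rng.normal(size=len(spurious)))
    for k, e in enumerate(spurious):
        rows.append(
            (regions[src[e]], regions[tgt[e]], w_sp[k], rng.uniform(0.05, 1.0))
        )
    return pd.DataFrame(rows, columns=["source", "target", "weight", "p"])


def _fc_from_structure(
    G: np.ndarray,
    density_terms: list[tuple[float, np.ndarray]],
    noise_sd: float,
    rng: np.random.Generator,
    comm_weight: float,
    state_term: tuple[float, np.ndarray] | None = None,
) -> np.ndarray:
    """Monotone (tanh) map of standardized communicability plus regional
    density terms and iid symmetric noise.

    The optional ``state_term``'s dyadic matrix is sample-orthogonalized
    against the other regressors (constant, communicability, base
    density terms) over the off-diagonal entries and rescaled to its
    original spread, so the state manipulation adds variance without
    in-sample crosstalk into the state-independent terms.
    """
    n = G.shape[0]
    Gs = (G + G.T) / 2
    off = ~np.eye(n, dtype=bool)
    z = np.zeros_like(Gs)
    z[off] = (Gs[off] - Gs[off].mean()) / Gs[off].std(ddof=1)
    design = [np.ones(off.sum()), z[off]]
    lin = comm_weight * z
    for w, u in density_terms:
        outer = (u[:, None] + u[None, :]) / 2
        lin = lin + w * (outer - outer[off].mean())
        design.append(outer[off])
    if state_term is not None:
        w, u = state_term
        outer = (u[:, None] + u[None, :]) / 2
        X = np.column_stack(design)
        v = outer[off]
        beta, _, _, _ = np.linalg.lstsq(X, v, rcond=None)
        resid = v - X @ beta
        P = np.zeros_like(outer)
        P[off] = resid * (v.std(ddof=1) / resid.std(ddof=1))
        P = (P + P.T) / 2
        lin = lin + w * P
    eps = rng.normal(scale=noise_sd, size=(n, n))
    lin = lin + (eps + eps.T) / 2
    F = np.tanh(lin)
    F = (F + F.T) / 2
    np.fill_diagonal(F, 0.0)
    return F


def gen_connectomes(
    config: SynthConfig, density: DensityMatrix
) -> tuple[StructuralConnectome, FunctionalConnectome, FunctionalConnectome]:
    """Generate the structural connectome and state-dependent functional
    connectomes.

    FC is a monotone (tanh) function of standardized communicability
    plus regional-density terms: long-lifetime PSD95 and SAP102 terms
    in both states, and a short-lifetime PSD95 term whose weight
    ``state_effect`` applies in the awake state only.
    """
    edges = gen_edge_candidates(config, density)
    sc = build_structural_connectome(
        edges, region_ids=list(density.values.columns), keep_significant=True
    )
    G = communicability(sc)
    maps = _derived_maps(density)
    u_long = _rank_unit(maps.loc["psd95_long"].values)
    u_short = _rank_unit(maps.loc["psd95_short"].values)
    u_sap = _rank_unit(maps.loc["sap102"].values)
    rng = np.random.default_rng(config.seed + 3)

    base_terms = [
        (config.fc_density_weight, u_long),
        (config.fc_density_weight, u_sap),
    ]
    # the anaesthetized state carries an equal-weight contribution from a
    # region-shuffled copy of the short-lifetime map (identical marginals,
    # unrelated to any real map): the state switch redistributes FC
    # variance rather than removing it, so only the short-lifetime term is
    # genuinely state-specific
    u_nuisance = rng.permutation(u_short)
    F_awake = _fc_from_structure(
        G,
        base_terms,
        config.fc_noise,
        rng,
        config.fc_comm_weight,
        state_term=(config.state_effect, u_short),
    )
    F_anaesth = _fc_from_structure(
        G,
        base_terms,
        config.fc_noise,
        rng,
        config.fc_comm_weight,
        state_term=(config.state_effect, u_nuisance),
    )
    ids = list(density.values.columns)
    return (
        sc,
        FunctionalConnectome(values=F_awake, region_ids=ids, state="awake"),
        FunctionalConnectome(values=F_anaesth, region_ids=ids, state="anaesthetized"),
    )


def gen_expression(
    config: SynthConfig, density: DensityMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix, dict]:
    """Generate sagittal/coronal expression matrices and category
    annotations with one planted density-coexpressed category.

    The planted category's genes are noisy linear transforms of the
    long-lifetime PSD95 density map; all other genes are smooth random
    maps.  The two section sources share the latent expression and
    differ by independent measurement noise; only a ``coronal_fraction``
    share of genes is measured coronally.
    """
    rng = np.random.default_rng(config.seed + 4)
    n_r, n_g = config.n_regions, config.n_genes
    if n_g < config.planted_category_size:
        raise ValueError("n_genes must cover the planted category")
    regions = list(density.values.columns)
    maps = _derived_maps(density)
    u_long = _rank_unit(maps.loc["psd95_long"].values)

    genes = [f"gene_{i:05d}" for i in range(n_g)]
    n_planted = config.planted_category_size
    # background: low-rank smooth maps + iid noise
    K = 6
    uu = np.arange(n_r) / n_r
    basis = np.stack(
        [np.sin(2 * np.pi * k * uu + rng.uniform(0, 2 * np.pi)) for k in range(1, K + 1)]
    )
    coefs = rng.normal(size=(n_g, K)) / np.arange(1, K + 1)
    latent = coefs @ basis + 0.5 * rng.normal(size=(n_g, n_r))
    # planted genes: monotone in the density map, gene-specific gain
    gain = rng.uniform(0.7, 1.3, size=n_planted)
    latent[:n_planted] = gain[:, None] * (
        u_long[None, :] + config.expr_noise * rng.normal(size=(n_planted, n_r))
    )

    sag = latent + config.source_noise * rng.normal(size=latent.shape)
    cor = latent + config.source_noise * rng.normal(size=latent.shape)
    n_cor = max(n_planted, int(round(config.coronal_fraction * n_g)))
    cor_idx = np.concatenate(
        [
            np.arange(n_planted),
            n_planted + rng.choice(n_g - n_planted, n_cor - n_planted, replace=False),
        ]
    )
    cor_idx.sort()

    sagittal = ExpressionMatrix(
        values=pd.DataFrame(sag, index=pd.Index(genes, name="gene"), columns=regions),
        source="sagittal",
    )
    coronal = ExpressionMatrix(
        values=pd.DataFrame(
            cor[cor_idx], index=pd.Index([genes[i] for i in cor_idx], name="gene"),
            columns=regions,
        ),
        source="coronal",
    )

    annotation: dict[str, list[str]] = {
        "cat_000_planted_synaptic": genes[:n_planted]
    }
    for c in range(1, config.n_categories):
        size = int(rng.integers(60, 251))
        members = rng.choice(n_g - n_planted, size=min(size, n_g - n_planted), replace=False)
        annotation[f"cat_{c:03d}"] = [genes[n_planted + i] for i in members]
    return sagittal, coronal, annotation


def gen_parcellation_hierarchy(
    n_fine: int = 775, n_coarse: int = 88, seed: int = 0
) -> pd.DataFrame:
    """A fine->coarse region table for testing parcellation aggregation.

    Every fine sample maps to exactly one parent; parents receive at
    least one child and the remainder are assigned at random.
    """
    if n_fine < n_coarse:
        raise ValueError("need at least one fine sample per parent")
    rng = np.random.default_rng(seed)
    parents = [f"R{i:03d}" for i in range(n_coarse)]
    assign = np.concatenate(
        [np.arange(n_coarse), rng.integers(0, n_coarse, size=n_fine - n_coarse)]
    )
    rng.shuffle(assign)
    ontology = region_ontology_labels(n_coarse)
    table = pd.DataFrame(
        {
            "parent_id": [parents[a] for a in assign],
            "ontology": [ontology.iloc[a] for a in assign],
        },
        index=pd.Index([f"F{i:04d}" for i in range(n_fine)], name="region_id"),
    )
    return table
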