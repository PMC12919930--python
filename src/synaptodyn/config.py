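"""Synthetic-study configuration and planted ground truth."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SynthConfig:
    """Parameters of the synthetic multiscale study.

    The default sizes mirror the study design the package analyses:
    37 synapse subtypes (11 PSD95, 7 SAP102, 19 colocalized), 10
    subjects with 88-region x 1414-time-point standardized signals, a
    ~7%-dense weighted directed structural connectome, awake and
    anaesthetized functional connectomes, and gene expression from two
    section sources with planted coexpressed categories.

    Effect parameters
    -----------------
    effect_statav : slope coupling the planted long-lifetime PSD95 map
        to the SD of per-segment mean offsets (drives StatAv).
    effect_outlier : slope coupling the planted SAP102 map to the
        lateness of injected negative spikes (drives outlier timing).
    state_effect : weight of the awake-only short-lifetime-density
        contribution to functional connectivity.
    map_jitter : SD of the region-level jitter added to a planted map
        before it drives a mechanism; dilutes the recoverable Spearman
        correlation to the target regime (~0.6 at the defaults).
    """

    n_regions: int = 88
    n_subjects: int = 10
    n_timepoints: int = 1414
    n_subtypes_psd95: int = 11
    n_subtypes_sap102: int = 7
    n_subtypes_coloc: int = 19
    effect_statav: float = 0.7
    effect_outlier: float = 3.0
    sc_density: float = 0.07
    state_effect: float = 0.5
    n_genes: int = 2000
    n_categories: int = 80
    seed: int = 0

    # nuisance / noise structure
    density_noise: float = 0.3  # within-cluster subtype map noise (latent SD units)
    map_jitter: float = 0.35  # regional jitter diluting planted effects
    statav_base: float = 0.05  # baseline segment-offset SD
    n_segments: int = 10
    event_rate: float = 40.0  # mean number of injected negative spikes
    spike_amp: float = 6.0  # spike amplitude in baseline-SD units
    ar_phi_low: float = 0.3  # per-region AR(1) coefficient range
    ar_phi_high: float = 0.9
    obs_noise_max: float = 0.7  # per-region white-noise amplitude range
    osc_max: float = 0.6  # per-region slow-oscillation amplitude range
    motion_coupling: float = 0.0  # contamination dial: FD leakage into signal
    snr_coupling: float = 0.0  # confound dial: SNR-dependent noise floor
    fc_comm_weight: float = 0.8
    fc_density_weight: float = 0.3  # state-independent density term in FC
    fc_noise: float = 0.15
    expr_noise: float = 0.4  # planted-gene noise (targets gene-density r ~ 0.6)
    source_noise: float = 0.2  # independent sagittal/coronal measurement noise
    planted_category_size: int = 120
    coronal_fraction: float = 0.5  # share of genes also measured coronally

    def __post_init__(self) -> None:
        counts = {
            "n_regions": self.n_regions,
            "n_subjects": self.n_subjects,
            "n_timepoints": self.n_timepoints,
            "n_subtypes_psd95": self.n_subtypes_psd95,
            "n_subtypes_sap102": self.n_subtypes_sap102,
            "n_subtypes_coloc": self.n_subtypes_coloc,
            "n_genes": self.n_genes,
            "n_categories": self.n_categories,
        }
        for name, v in counts.items():
            if int(v) != v or v < 2:
                raise ValueError(f"{name} must be an integer >= 2, got {v}")
        if not 0 < self.sc_density <= 1:
            raise ValueError("sc_density must be in (0, 1]")
        if self.n_segments < 2:
            raise ValueError("n_segments must be >= 2")

    @property
    def n_subtypes(self) -> int:
        return self.n_subtypes_psd95 + self.n_subtypes_sap102 + self.n_subtypes_coloc


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery tests.

    ``planted_cluster_of_subtype`` labels each subtype with its latent
    cluster; ``planted_maps`` holds the region-indexed latent maps
    (psd95_long, psd95_short, sap102, ...); ``lifetimes`` the per-PSD95
    subtype protein lifetime (% puncta remaining after 7 days);
    ``true_effects`` the effect slopes in force.
    """

    planted_cluster_of_subtype: pd.Series
    planted_maps: pd.DataFrame
    lifetimes: pd.Series
    true_effects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lt = self.lifetimes.dropna()
        if ((lt < 0) | (lt > 100)).any():
            raise ValueError("lifetimes must lie in [0, 100] percent")
        if not np.isfinite(self.planted_maps.to_numpy(dtype=float)).all():
            raise ValueError("planted maps must be finite")
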