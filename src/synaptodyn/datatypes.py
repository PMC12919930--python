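"""Core data containers.

Thin dataclasses around pandas/numpy objects.  Tabular data (density
matrices, feature matrices, region tables) live in labelled DataFrames;
dense numeric blocks (time-series stacks, adjacency matrices) in numpy
arrays with explicit id lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROTEIN_CLASSES = ("PSD95", "SAP102", "coloc")

#: canonical subtype layout: 11 PSD95, 7 SAP102, 19 colocalized
CANONICAL_SUBTYPE_COUNTS = {"PSD95": 11, "SAP102": 7, "coloc": 19}


@dataclass
class DensityMatrix:
    """Synapse-subtype density maps.

    Attributes
    ----------
    values : DataFrame, subtype x region
        Nonnegative puncta densities.
    subtype_meta : DataFrame indexed like ``values``
        Columns: ``protein_class`` (PSD95 | SAP102 | coloc) and
        ``lifetime`` (% of tagged puncta remaining after 7 days; PSD95
        subtypes only, NaN elsewhere).  Generators may add a
        ``planted_cluster`` column.
    region_ontology : Series, region -> major-structure label (optional)
    """

    values: pd.DataFrame
    subtype_meta: pd.DataFrame
    region_ontology: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("densities must be nonnegative")
        if not self.values.index.equals(self.subtype_meta.index):
            raise ValueError("subtype_meta index must match values index")
        bad = set(self.subtype_meta["protein_class"]) - set(PROTEIN_CLASSES)
        if bad:
            raise ValueError(f"unknown protein classes: {bad}")

    @property
    def regions(self) -> pd.Index:
        return self.values.columns

    def class_rows(self, protein_class: str) -> pd.DataFrame:
        mask = self.subtype_meta["protein_class"] == protein_class
        return self.values.loc[mask]


@dataclass
class TimeSeriesStack:
    """Per-subject regional signals, subject x region x time.

    ``motion`` holds per-subject frame-wise displacement traces of
    length T-1 (mm); ``snr`` an optional regional signal-to-noise map.
    """

    values: np.ndarray
    region_ids: list
    subject_ids: list
    state: list  # per subject: "awake" | "anaesthetized"
    motion: np.ndarray | None = None  # subjects x (T-1)
    snr: pd.Series | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be subject x region x time")
        s, r, t = self.values.shape
        if len(self.region_ids) != r or len(self.subject_ids) != s:
            raise ValueError("id lists do not match array shape")
        if len(self.state) != s:
            raise ValueError("one state label per subject required")
        if not np.isfinite(self.values).all():
            raise ValueError("time-series contain non-finite values")
        if self.motion is not None:
            self.motion = np.asarray(self.motion, dtype=float)
            if self.motion.shape != (s, t - 1):
                raise ValueError("motion must be subjects x (T-1)")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[2]

    def subset_state(self, state: str) -> "TimeSeriesStack":
        keep = [i for i, st in enumerate(self.state) if st == state]
        if not keep:
            raise ValueError(f"no subjects in state {state!r}")
        return TimeSeriesStack(
            values=self.values[keep],
            region_ids=list(self.region_ids),
            subject_ids=[self.subject_ids[i] for i in keep],
            state=[self.state[i] for i in keep],
            motion=None if self.motion is None else self.motion[keep],
            snr=self.snr,
        )


@dataclass
class FeatureMatrix:
    """Region x feature matrix with a feature catalog.

    ``catalog`` is indexed by feature name with at least a ``family``
    column.  Missing cells (failed feature evaluations) are NaN.  When
    ``normalized`` is True all finite values lie in [0, 1].
    """

    values: pd.DataFrame
    catalog: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.catalog.index)
        if missing:
            raise ValueError(f"features absent from catalog: {missing}")
        if self.normalized:
            v = self.values.values
            finite = v[np.isfinite(v)]
            if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
                raise ValueError("normalized features must lie in [0, 1]")


@dataclass
class StructuralConnectome:
    """Weighted directed structural adjacency with per-edge p-values."""

    weights: np.ndarray  # source x target, zero diagonal
    pvalues: np.ndarray  # NaN where no candidate edge was offered
    region_ids: list

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.region_ids)
        if self.weights.shape != (n, n):
            raise ValueError("weights must be square over region_ids")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("self-connections are not allowed")
        if (self.weights < 0).any():
            raise ValueError("weights must be nonnegative")

    @property
    def density(self) -> float:
        n = self.weights.shape[0]
        off = n * (n - 1)
        return float((self.weights != 0).sum() / off)


@dataclass
class FunctionalConnectome:
    """Symmetric functional correlation matrix, zero diagonal."""

    values: np.ndarray
    region_ids: list
    state: str = "awake"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.region_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix must be square over region_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("functional connectome must be symmetric")
        if np.abs(self.values).max() > 1 + 1e-9:
            raise ValueError("entries must lie in [-1, 1]")


@dataclass
class ExpressionMatrix:
    """Gene x region expression values from one section source."""

    values: pd.DataFrame
    source: str = "sagittal"  # sagittal | coronal
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.source not in ("sagittal", "coronal"):
            raise ValueError("source must be 'sagittal' or 'coronal'")
        if self.normalized:
            v = self.values.values
            finite = v[np.isfinite(v)]
            if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
                raise ValueError("normalized expression must lie in [0, 1]")


@dataclass
class CouplingResult:
    """Per-region structure-function coupling fits.

    ``table`` columns: ``r2_base`` (communicability-only adjusted R^2),
    ``r2_aug`` (with synapse regressors), ``delta`` (their difference)
    and ``flagged`` (collinear / degenerate fits).
    """

    table: pd.DataFrame
    regressors: list = field(default_factory=list)
    n_obs: int = 0
    n_predictors_aug: int = 0
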