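"""Time-series feature catalog and region x feature matrices.

A curated set of interpretable scalar statistics of a regional signal:
mean-stationarity (StatAv), outlier-event timing, local-vs-global
variance, detrended fluctuation scaling, distribution moments and lag-k
autocorrelations.  Each feature is computed per region and subject,
normalized across regions with a scaled robust sigmoid, and averaged
across subjects.

Conventions: sample SD (ddof=1) throughout; features that fail on a
series (degenerate input) are recorded as missing, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import (
    DegenerateSeriesError,
    robust_sigmoid_columns,
    sd,
    zscore,
)
from .datatypes import FeatureMatrix, TimeSeriesStack

__all__ = [
    "zscore",
    "statav",
    "outlier_timing_mrmd",
    "local_global_std",
    "dfa_scaling",
    "loglog_fit",
    "OutlierTimingParams",
    "default_catalog",
    "compute_feature_matrix",
    "normalize_features",
    "group_average",
]


def statav(series: np.ndarray, n: int) -> float:
    """Mean-stationarity statistic StatAv(n).

    The series is cut into ``n`` equally sized non-overlapping segments
    (trailing remainder points are discarded from the segments); the SD
    of the ``n`` segment means is divided by the SD of the full series.
    Low values indicate a stationary mean.
    """
    x = np.asarray(series, dtype=float)
    if n < 2:
        raise ValueError("need at least 2 segments")
    if x.size < 2 * n:
        raise ValueError("series too short for the requested segments")
    full_sd = sd(x)
    if full_sd == 0:
        raise DegenerateSeriesError("constant series")
    seg_len = x.size // n
    means = x[: n * seg_len].reshape(n, seg_len).mean(axis=1)
    return float(sd(means) / full_sd)


@dataclass(frozen=True)
class OutlierTimingParams:
    """Threshold grid for the outlier-event timing statistic."""

    increment: float = 0.01
    theta_min: float = -3.5
    sign: str = "negative"

    def __post_init__(self) -> None:
        if self.increment <= 0:
            raise ValueError("increment must be positive")
        if self.sign not in ("negative", "positive"):
            raise ValueError("sign must be 'negative' or 'positive'")
        if self.sign == "negative" and self.theta_min >= 0:
            raise ValueError("theta_min must be negative for the negative variant")


def outlier_timing_mrmd(
    series: np.ndarray, params: OutlierTimingParams = OutlierTimingParams()
) -> float:
    """Median (over thresholds) of the mean normalized time of extreme events.

    The series is z-scored and time is mapped to [-1, 1].  For each
    threshold theta on a grid from 0 down to ``theta_min`` (negative
    variant), the points with z <= theta are selected and their mean
    time recorded; the statistic is the median of those means over all
    thresholds that select at least one point.  Positive values mean
    extreme events occur late in the recording.

    The positive variant mirrors the construction with z >= theta,
    theta from 0 up to ``|theta_min|``.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    z = zscore(x)
    t = 2.0 * np.arange(x.size) / (x.size - 1) - 1.0
    if params.sign == "negative":
        vals = z
    else:
        vals = -z
    n_thresh = int(round(abs(params.theta_min) / params.increment)) + 1
    thresholds = -params.increment * np.arange(n_thresh)
    # selection sets are prefixes of the series sorted by value
    order = np.argsort(vals, kind="stable")
    sorted_vals = vals[order]
    cum_t = np.cumsum(t[order])
    counts = np.searchsorted(sorted_vals, thresholds, side="right")
    nonempty = counts > 0
    if not nonempty.any():
        raise DegenerateSeriesError("no threshold selects any point")
    means = cum_t[counts[nonempty] - 1] / counts[nonempty]
    return float(np.median(means))


def local_global_std(series: np.ndarray, fraction: float = 0.01) -> float:
    """SD of the initial ``fraction`` of the series over the full-series SD."""
    x = np.asarray(series, dtype=float)
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    k = int(np.ceil(fraction * x.size))
    if k < 2:
        raise ValueError("initial segment shorter than 2 points")
    full_sd = sd(x)
    if full_sd == 0:
        raise DegenerateSeriesError("constant series")
    return float(sd(x[:k]) / full_sd)


def dfa_scaling(
    series: np.ndarray, min_window: int = 50, n_scales: int = 12
) -> tuple[float, float]:
    """Detrended fluctuation analysis scaling exponent and fit residual.

    The integrated (cumulatively summed, mean-removed) series is cut
    into non-overlapping windows at scales log-spaced from
    ``min_window`` to T/4; each window is linearly detrended and the
    RMS fluctuation F(w) recorded.  Returns the slope alpha of
    log F vs log w (0.5 for white noise, 1.5 for a random walk) and the
    sum of squared residuals of that log-log fit.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 4 * min_window:
        raise ValueError("series too short for DFA")
    y = np.cumsum(x - x.mean())
    scales = np.unique(
        np.round(
            np.exp(np.linspace(np.log(min_window), np.log(x.size // 4), n_scales))
        ).astype(int)
    )
    fluct = np.empty(len(scales))
    for i, w in enumerate(scales):
        n_win = y.size // w
        seg = y[: n_win * w].reshape(n_win, w)
        tt = np.arange(w, dtype=float)
        tc = tt - tt.mean()
        denom = (tc**2).sum()
        slope = (seg * tc).sum(axis=1) / denom
        inter = seg.mean(axis=1)
        resid = seg - (inter[:, None] + slope[:, None] * tc[None, :])
        fluct[i] = np.sqrt((resid**2).mean())
    return loglog_fit(scales, fluct)


def loglog_fit(scales: np.ndarray, flucts: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and residual SSR of log F(w) vs log w."""
    logw = np.log(np.asarray(scales, dtype=float))
    logf = np.log(np.asarray(flucts, dtype=float))
    X = np.column_stack([np.ones_like(logw), logw])
    beta, _, _, _ = np.linalg.lstsq(X, logf, rcond=None)
    resid = logf - X @ beta
    return float(beta[1]), float((resid**2).sum())


def _autocorr(series: np.ndarray, lag: int) -> float:
    x = np.asarray(series, dtype=float)
    if x.size <= lag + 1:
        raise ValueError("series too short for requested lag")
    xc = x - x.mean()
    denom = (xc**2).sum()
    if denom == 0:
        raise DegenerateSeriesError("constant series")
    return float((xc[:-lag] * xc[lag:]).sum() / denom)


def default_catalog() -> pd.DataFrame:
    """The default feature catalog: name -> (family, callable).

    Families tag features measuring the same phenomenon; the
    representative-feature selector reports them.
    """
    entries: dict[str, tuple[str, object]] = {}
    for n in range(2, 11):
        entries[f"statav_{n}"] = ("statav", lambda x, n=n: statav(x, n))
    entries["outlier_timing_neg_mrmd"] = (
        "outlier_timing",
        lambda x: outlier_timing_mrmd(x, OutlierTimingParams(sign="negative")),
    )
    entries["outlier_timing_pos_mrmd"] = (
        "outlier_timing",
        lambda x: outlier_timing_mrmd(
            x, OutlierTimingParams(theta_min=-3.5, sign="positive")
        ),
    )
    for frac in (0.01, 0.05, 0.1):
        entries[f"local_global_std_{frac}"] = (
            "local_global",
            lambda x, f=frac: local_global_std(x, f),
        )
    entries["dfa_alpha"] = ("fluctuation", lambda x: dfa_scaling(x)[0])
    entries["dfa_loglog_ssr"] = ("fluctuation", lambda x: dfa_scaling(x)[1])
    entries["mean"] = ("distribution", lambda x: float(np.mean(x)))
    entries["std"] = ("distribution", lambda x: float(sd(x)))
    entries["skewness"] = ("distribution", lambda x: float(stats.skew(x)))
    entries["kurtosis"] = ("distribution", lambda x: float(stats.kurtosis(x)))
    entries["min"] = ("distribution", lambda x: float(np.min(x)))
    entries["max"] = ("distribution", lambda x: float(np.max(x)))
    for lag in (1, 2, 3, 5, 10):
        entries[f"autocorr_lag{lag}"] = (
            "autocorrelation",
            lambda x, l=lag: _autocorr(x, l),
        )
    cat = pd.DataFrame(
        {
            "family": [fam for fam, _ in entries.values()],
            "func": [fn for _, fn in entries.values()],
        },
        index=pd.Index(entries.keys(), name="feature"),
    )
    return cat


def compute_feature_matrix(
    stack: TimeSeriesStack, catalog: pd.DataFrame | None = None
) -> list[FeatureMatrix]:
    """Evaluate the catalog on every (subject, region) series.

    Returns one region x feature matrix per subject.  Features that
    raise on a series are recorded as NaN.  Features with zero variance
    across regions in *any* subject are dropped from *all* subjects, so
    the matrices stay aligned.
    """
    if catalog is None:
        catalog = default_catalog()
    if stack.n_timepoints < 100:
        raise ValueError("need at least 100 time points for feature extraction")
    names = list(catalog.index)
    funcs = list(catalog["func"])
    mats = []
    for s in range(stack.values.shape[0]):
        out = np.full((len(stack.region_ids), len(names)), np.nan)
        for r in range(len(stack.region_ids)):
            x = stack.values[s, r]
            for j, fn in enumerate(funcs):
                try:
                    out[r, j] = fn(x)
                except (DegenerateSeriesError, ValueError):
                    pass
        mats.append(
            pd.DataFrame(out, index=list(stack.region_ids), columns=names)
        )
    # drop zero-variance (or all-missing) features, mirrored across subjects
    keep = []
    for name in names:
        ok = True
        for m in mats:
            col = m[name].dropna()
            tol = 1e-12 * max(1.0, np.abs(col.values).max()) if len(col) else 0.0
            if len(col) == 0 or np.nanstd(col.values) <= tol:
                ok = False
                break
        if ok:
            keep.append(name)
    cat_out = catalog.loc[keep, ["family"]].copy()
    return [
        FeatureMatrix(values=m[keep], catalog=cat_out, normalized=False)
        for m in mats
    ]


def normalize_features(matrix: FeatureMatrix) -> FeatureMatrix:
    """Scaled robust sigmoid normalization of each feature across regions.

    Per feature: ``1 / (1 + exp(-(x - median) / (IQR / 1.349)))`` then a
    min-max rescale to [0, 1].  If the IQR is zero the SD is used in its
    place; if both are zero the feature is dropped.
    """
    if matrix.values.shape[0] < 3:
        raise ValueError("need at least 3 regions to normalize")
    scaled, dropped = robust_sigmoid_columns(matrix.values.values)
    keep = ~dropped
    cols = matrix.values.columns[keep]
    vals = pd.DataFrame(
        scaled[:, keep], index=matrix.values.index, columns=cols
    )
    return FeatureMatrix(
        values=vals, catalog=matrix.catalog.loc[cols], normalized=True
    )


def group_average(matrices: list[FeatureMatrix]) -> FeatureMatrix:
    """Element-wise mean across subjects, ignoring missing cells."""
    if not matrices:
        raise ValueError("empty matrix list")
    first = matrices[0]
    for m in matrices[1:]:
        if not m.values.index.equals(first.values.index) or not m.values.columns.equals(
            first.values.columns
        ):
            raise ValueError("matrices must share regions and features")
    stack = np.stack([m.values.values for m in matrices])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    vals = pd.DataFrame(mean, index=first.values.index, columns=first.values.columns)
    return FeatureMatrix(
        values=vals, catalog=first.catalog, normalized=first.normalized
    )
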