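"""Shared statistical primitives.

Conventions used throughout the package, centralized here:

* sample standard deviation (``ddof=1``) everywhere;
* average ranks for ties; the median of an even-count set is the mean of
  the two central values;
* quartiles by linear interpolation (type-7, numpy's default);
* the "normalized IQR" divides the raw IQR by 1.349, the IQR of a
  standard normal, so that it estimates sigma.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

#: IQR of the standard normal distribution; IQR / NORMAL_IQR estimates sigma.
NORMAL_IQR = 1.349


class DegenerateSeriesError(ValueError):
    """Raised when an operation is undefined on the given series
    (e.g. zero variance where a normalization is required)."""


def sd(x: np.ndarray, axis=None) -> np.ndarray:
    """Sample standard deviation (ddof=1)."""
    return np.std(x, axis=axis, ddof=1)


def zscore(x: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, sample SD 1.

    Raises
    ------
    DegenerateSeriesError
        If the series is constant (SD = 0) or shorter than 2 points.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise DegenerateSeriesError("need at least 2 points to z-score")
    s = sd(x)
    if s == 0 or not np.isfinite(s):
        raise DegenerateSeriesError("constant series cannot be z-scored")
    return (x - x.mean()) / s


def rankdata_2d(a: np.ndarray) -> np.ndarray:
    """Column-wise average ranks of a 2-D array (rows = observations)."""
    return np.apply_along_axis(stats.rankdata, 0, np.asarray(a, dtype=float))


def spearman_vector(x: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Spearman r of ``x`` against every column of ``ys`` (vectorized).

    Columns with zero rank variance yield NaN.
    """
    x = np.asarray(x, dtype=float)
    ys = np.asarray(ys, dtype=float)
    rx = stats.rankdata(x)
    ry = rankdata_2d(ys)
    rx = rx - rx.mean()
    ry = ry - ry.mean(axis=0)
    denom = np.sqrt((rx**2).sum()) * np.sqrt((ry**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (rx @ ry) / denom
    return r


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman r and two-sided p (t approximation), NaN-pair-safe."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return float("nan"), float("nan")
    res = stats.spearmanr(x[ok], y[ok])
    return float(res.statistic), float(res.pvalue)


def bonferroni(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Bonferroni-corrected p-values, capped at 1.

    ``m`` defaults to the number of finite p-values in ``p``.
    """
    p = np.asarray(p, dtype=float)
    if m is None:
        m = int(np.isfinite(p).sum())
    return np.minimum(p * m, 1.0)


def robust_sigmoid_columns(
    values: np.ndarray, rescale: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled robust sigmoid normalization, applied per column.

    Each column x is mapped through ``1 / (1 + exp(-(x - median) / scale))``
    with ``scale = IQR / 1.349`` (falling back to the sample SD when the IQR
    is zero), then min-max rescaled to [0, 1].  Columns that are constant
    (both IQR and SD zero) cannot be normalized; they are returned as NaN
    and flagged in the second return value.

    Returns
    -------
    scaled : ndarray
        Normalized array, NaN where the input was NaN or the column constant.
    dropped : ndarray of bool
        True for columns that could not be normalized.
    """
    x = np.asarray(values, dtype=float)
    med = np.nanmedian(x, axis=0)
    q1, q3 = np.nanpercentile(x, [25, 75], axis=0)
    scale = (q3 - q1) / NORMAL_IQR
    sd_col = np.nanstd(x, axis=0, ddof=1)
    # effectively-constant columns: spread at float-noise level
    tol = 1e-12 * np.maximum(1.0, np.abs(med))
    scale = np.where(scale > tol, scale, sd_col)
    dropped = ~(scale > tol)
    safe = np.where(dropped, 1.0, scale)
    with np.errstate(over="ignore"):
        norm = 1.0 / (1.0 + np.exp(-(x - med) / safe))
    norm[:, dropped] = np.nan
    if not rescale:
        return norm, dropped
    lo = np.nanmin(norm, axis=0)
    hi = np.nanmax(norm, axis=0)
    rng = hi - lo
    rng = np.where(rng > 0, rng, 1.0)
    scaled = (norm - lo) / rng
    return scaled, dropped


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted R^2 for n observations and p predictors."""
    if n - p - 1 <= 0:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    """Plain R^2 of an OLS fit of y on columns of X (intercept added)."""
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones(len(y)), np.asarray(X, dtype=float)])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sst = ((y - y.mean()) ** 2).sum()
    if sst == 0:
        return float("nan")
    return 1.0 - (resid**2).sum() / sst
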