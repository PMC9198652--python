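"""Scalar summaries of feature time series.

Each time-series feature is reduced to scalars with the robust battery
used throughout handwriting analysis: median, interquartile range
(iqr = P75 - P25), the nonparametric coefficient of variation
(ncv = iqr / median), the Theil-Sen slope against time, and — for
kinematic series only — the 95th percentile.  Percentiles use linear
interpolation between order statistics.

Undefined values (ncv at zero median, slope of a single point, any
statistic of an empty series) are returned as NaN rather than +-inf so
downstream imputation can treat them uniformly as missing.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["aggregate_series", "theil_sen_slope", "BASE_STATS", "KINEMATIC_STATS"]

BASE_STATS = ("median", "iqr", "ncv", "slope")
KINEMATIC_STATS = BASE_STATS + ("95p",)

# Above this length the O(n^2) pairwise-slope median is replaced by a
# seeded random subsample of pairs.
_TS_MAX_EXACT = 2000
_TS_N_PAIRS = 1_000_000
_TS_SEED = 0x5EED


def theil_sen_slope(y: np.ndarray, t: np.ndarray) -> float:
    """Median of all pairwise slopes (y_j - y_i) / (t_j - t_i), i < j.

    For more than _TS_MAX_EXACT samples the median is taken over a
    fixed-seed random subsample of one million pairs.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    if len(y) < 2:
        return np.nan
    if len(y) <= _TS_MAX_EXACT:
        return float(stats.theilslopes(y, t).slope)
    rng = np.random.default_rng(_TS_SEED)
    i = rng.integers(0, len(y), size=_TS_N_PAIRS)
    j = rng.integers(0, len(y), size=_TS_N_PAIRS)
    keep = t[i] != t[j]
    return float(np.median((y[j][keep] - y[i][keep]) / (t[j][keep] - t[i][keep])))


def aggregate_series(
    series: np.ndarray,
    t: np.ndarray | None = None,
    statistics: tuple[str, ...] = BASE_STATS,
) -> dict[str, float]:
    """Reduce one series to the named scalar statistics.

    ``t`` (seconds) is required for the slope; when omitted the slope is
    NaN.  Any statistic of an empty series is NaN, and ncv is NaN when
    the median is exactly zero.
    """
    series = np.asarray(series, dtype=float)
    finite = np.isfinite(series)
    series = series[finite]
    if t is not None:
        t = np.asarray(t, dtype=float)[finite]
    out: dict[str, float] = {}
    empty = len(series) == 0
    for stat in statistics:
        if empty:
            out[stat] = np.nan
        elif stat == "median":
            out[stat] = float(np.median(series))
        elif stat == "iqr":
            out[stat] = float(np.percentile(series, 75) - np.percentile(series, 25))
        elif stat == "ncv":
            med = np.median(series)
            iqr = np.percentile(series, 75) - np.percentile(series, 25)
            out[stat] = float(iqr / med) if med != 0 else np.nan
        elif stat == "95p":
            out[stat] = float(np.percentile(series, 95))
        elif stat == "slope":
            if t is None or len(series) < 2:
                out[stat] = np.nan
            else:
                out[stat] = theil_sen_slope(series, t)
        else:
            raise ValueError(f"unknown statistic {stat!r}")
    return out
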