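"""Archimedean-spiral drawing metrics.

The spiral drawing task is the standard language-independent probe of
tremor and motor control: the subject traces an Archimedean spiral
r = c0 + c1*theta.  After a polar transform about the estimated spiral
centre, the radius is resampled on a uniform angle grid and an ideal
linear spiral is fitted; the metrics summarise the residual wobble
(tremor), the radial growth rate, and overall precision:

TGHTNS   fitted radial growth c1 (mm/rad)
1stSm    std of the first difference of the residual (first-order
         smoothness; larger = rougher)
2ndSm    std of the second difference of the residual
1stZC    zero-crossings of the residual first difference per radian
2ndZC    zero-crossings of the residual second difference per radian
DoS      RMS residual normalised by the fitted radial range
         (degree of severity)
MDS      mean drawing speed = on-surface path length / duration (mm/s)
SWVI     iqr of the loop-to-loop radial gap r(theta+2pi) - r(theta)
SPI      1 - RMS residual / mean fitted radius, clipped to [0, 1]
         (spiral precision index)

Centre estimation starts at the centroid of the on-surface points and
is refined by regressing r on {1, theta, cos theta, sin theta}: for a
small centre offset (dx, dy) the radius picks up an additive
dx*cos(theta) + dy*sin(theta) term, so shifting the centre by the
fitted harmonic coefficients removes it.  A few refinement passes
reduce the residual of an ideally drawn spiral to the millidegree
level, at which point DoS vanishes and SPI reaches 1 within 1e-3.

All metrics require at least one full revolution of unwrapped
on-surface angle; otherwise every spiral feature is missing.
"""

from __future__ import annotations

import numpy as np

from .geometry import polyline_length
from .records import HandwritingRecord, Stroke, strokes_of

__all__ = ["spiral_features", "SPIRAL_FEATURES"]

SPIRAL_FEATURES = (
    "1stSm", "2ndSm", "TGHTNS", "1stZC", "2ndZC", "DoS", "MDS", "SWVI", "SPI",
)

_DTHETA = np.pi / 180.0


def _refine_center(x: np.ndarray, y: np.ndarray, n_iter: int = 8):
    """Estimate the spiral centre: centroid + harmonic refinement."""
    cx, cy = float(np.mean(x)), float(np.mean(y))
    for _ in range(n_iter):
        dx, dy = x - cx, y - cy
        r = np.hypot(dx, dy)
        theta = np.unwrap(np.arctan2(dy, dx))
        design = np.column_stack(
            [np.ones_like(theta), theta, np.cos(theta), np.sin(theta)]
        )
        coef, *_ = np.linalg.lstsq(design, r, rcond=None)
        cx += coef[2]
        cy += coef[3]
    return cx, cy


def _zero_crossings(v: np.ndarray) -> int:
    s = np.sign(v)
    s = s[s != 0]
    if len(s) < 2:
        return 0
    return int(np.count_nonzero(np.diff(s) != 0))


def spiral_features(
    record: HandwritingRecord, strokes: list[Stroke]
) -> tuple[dict[str, float], list[str]]:
    """Compute the spiral battery; returns (values, qc warnings).

    Values are all-NaN (with a warning) when the on-surface trace spans
    less than one full revolution.
    """
    missing = {name: np.nan for name in SPIRAL_FEATURES}
    on = strokes_of(strokes, "on_surface")
    if not on:
        return missing, ["spiral: no on-surface samples"]

    idx = np.concatenate([np.arange(s.start_index, s.end_index + 1) for s in on])
    x, y = record.x[idx], record.y[idx]

    cx, cy = _refine_center(x, y)
    dx, dy = x - cx, y - cy
    r = np.hypot(dx, dy)
    # the polar angle is ill-conditioned where the trace passes (almost)
    # through the centre; skip the innermost lead-in before unwrapping
    ok = np.flatnonzero(r >= 0.05 * r.max())
    if len(ok) < 10:
        return missing, ["spiral: trace never leaves the centre region"]
    dx, dy, r = dx[ok[0]:], dy[ok[0]:], r[ok[0]:]
    theta = np.unwrap(np.arctan2(dy, dx))
    if theta[-1] < theta[0]:  # clockwise drawing
        theta = -theta
    span = theta[-1] - theta[0]
    if span < 2 * np.pi:
        return missing, [
            f"spiral: unwrapped angle span {span:.2f} rad < one revolution"
        ]

    # monotone angle for interpolation: hesitations may locally reverse it
    theta_mono = np.maximum.accumulate(theta)
    uniq = np.concatenate(([True], np.diff(theta_mono) > 0))
    grid = np.arange(theta_mono[uniq][0], theta_mono[uniq][-1], _DTHETA)
    r_grid = np.interp(grid, theta_mono[uniq], r[uniq])

    design = np.column_stack([np.ones_like(grid), grid])
    (c0, c1), *_ = np.linalg.lstsq(design, r_grid, rcond=None)
    r_hat = c0 + c1 * grid
    e = r_grid - r_hat
    rms = float(np.sqrt(np.mean(e**2)))

    de = np.diff(e)
    d2e = np.diff(e, n=2)
    r_range = float(np.ptp(r_hat))
    span_grid = grid[-1] - grid[0]

    out = {
        "TGHTNS": float(c1),
        "1stSm": float(np.std(de)) if len(de) else np.nan,
        "2ndSm": float(np.std(d2e)) if len(d2e) else np.nan,
        "1stZC": _zero_crossings(de) / span_grid,
        "2ndZC": _zero_crossings(d2e) / span_grid,
        "DoS": rms / r_range if r_range > 0 else np.nan,
        "SPI": float(np.clip(1.0 - rms / np.mean(r_hat), 0.0, 1.0))
        if np.mean(r_hat) > 0
        else np.nan,
    }

    # loop-to-loop width variability
    lag = int(round(2 * np.pi / _DTHETA))
    if len(r_grid) > lag:
        gaps = r_grid[lag:] - r_grid[:-lag]
        out["SWVI"] = float(np.percentile(gaps, 75) - np.percentile(gaps, 25))
    else:
        out["SWVI"] = np.nan

    length = sum(
        polyline_length(np.column_stack([record.x[s.sl], record.y[s.sl]]))
        for s in on
    )
    dur = sum(s.duration(record) for s in on)
    out["MDS"] = length / dur if dur > 0 else np.nan

    return out, []
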