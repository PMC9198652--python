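"""The handcrafted online-handwriting feature battery.

Families:

* temporal — writing durations per surface class (DUR), on/in-air
  duration ratio (DURR), per-stroke durations (SDUR) and adjacent
  on/in-air stroke duration ratios (SDURR)
* spatial — product width/height/length per class (WIDTH, HEIGHT, LEN)
  and their per-stroke counterparts (SWIDTH, SHEIGHT, SLEN)
* kinematic — velocity, angular velocity, acceleration (VEL, AVEL,
  ACC), per class, with horizontal/vertical projections
* dynamic — pressure, tilt, azimuth (PRESS, TILT, AZIM)
* other — interruption counts (NINT, RNINT), polyline intersection
  counts (NIEI, NIAI, TNIAI and relative variants), profile change
  rates (RNCV, RNCP, RNCT, RNCA)
* spiral-specific (spiral task only) — see :mod:`graphomotor.spiral`

Feature names follow ``INF:DIR-FN(HL)``: the information source (ON /
AIR / PRESS / TILT / AZIM), the optional direction (H / V), the feature
name, and the aggregation statistic.  Time-series features are reduced
by median, iqr, ncv = iqr/median and the Theil-Sen slope; kinematic
series additionally by the 95th percentile.

Derivatives are computed strictly within strokes and concatenated —
differencing across a pen lift would fabricate enormous velocities.
Event counts are normalised per second of on-surface time (temporal
events) or per millimetre of on-surface path (geometric events).
Features that are undefined on a record (e.g. DURR without in-air
movement, ncv at zero median) are carried as NaN; model evaluation
imputes them with training-fold medians.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aggregates import BASE_STATS, KINEMATIC_STATS, aggregate_series
from .geometry import count_polyline_intersections, polyline_length
from .records import HandwritingRecord, Stroke, segment_strokes, strokes_of
from .spiral import SPIRAL_FEATURES, spiral_features

__all__ = [
    "FeatureVector",
    "temporal_features",
    "spatial_features",
    "kinematic_features",
    "dynamic_features",
    "profile_change_counts",
    "interruption_features",
    "intersection_features",
    "extract_feature_vector",
    "feature_names",
]

_CLASSES = (("ON", "on_surface"), ("AIR", "in_air"))


@dataclass
class FeatureVector:
    """Named scalar features of one recording."""

    values: dict[str, float]
    task: str
    subject_id: str
    qc: list[str] = field(default_factory=list)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def names(self) -> list[str]:
        return list(self.values)


def _stroke_points(record: HandwritingRecord, stroke: Stroke) -> np.ndarray:
    return np.column_stack([record.x[stroke.sl], record.y[stroke.sl]])


def _agg_into(
    out: dict[str, float],
    prefix: str,
    series,
    t=None,
    statistics=BASE_STATS,
) -> None:
    for stat, value in aggregate_series(
        np.asarray(series, float), None if t is None else np.asarray(t, float),
        statistics,
    ).items():
        out[f"{prefix}({stat})"] = value


# ---------------------------------------------------------------- temporal


def temporal_features(
    record: HandwritingRecord, strokes: list[Stroke]
) -> dict[str, float]:
    out: dict[str, float] = {}
    durs = {}
    for inf, kind in _CLASSES:
        ss = strokes_of(strokes, kind)
        d = [s.duration(record) for s in ss]
        starts = [record.t[s.start_index] for s in ss]
        durs[inf] = sum(d)
        out[f"{inf}:DUR"] = sum(d) if ss else np.nan
        _agg_into(out, f"{inf}:SDUR", d, starts)
    out["DURR"] = (
        durs["ON"] / durs["AIR"]
        if strokes_of(strokes, "in_air") and durs["AIR"] > 0
        else np.nan
    )
    # pairwise on-stroke / following in-air-stroke duration ratios
    ratios, rt = [], []
    for a, b in zip(strokes, strokes[1:]):
        if a.kind == "on_surface" and b.kind == "in_air":
            db = b.duration(record)
            if db > 0:
                ratios.append(a.duration(record) / db)
                rt.append(record.t[a.start_index])
    _agg_into(out, "SDURR", ratios, rt)
    return out


# ----------------------------------------------------------------- spatial


def spatial_features(
    record: HandwritingRecord, strokes: list[Stroke]
) -> dict[str, float]:
    out: dict[str, float] = {}
    for inf, kind in _CLASSES:
        ss = strokes_of(strokes, kind)
        if not ss:
            for fn in ("WIDTH", "HEIGHT", "LEN"):
                out[f"{inf}:{fn}"] = np.nan
            for fn in ("SWIDTH", "SHEIGHT", "SLEN"):
                _agg_into(out, f"{inf}:{fn}", [])
            continue
        idx = np.concatenate(
            [np.arange(s.start_index, s.end_index + 1) for s in ss]
        )
        out[f"{inf}:WIDTH"] = float(np.ptp(record.x[idx]))
        out[f"{inf}:HEIGHT"] = float(np.ptp(record.y[idx]))
        out[f"{inf}:LEN"] = sum(
            polyline_length(_stroke_points(record, s)) for s in ss
        )
        starts = [record.t[s.start_index] for s in ss]
        _agg_into(out, f"{inf}:SWIDTH",
                  [float(np.ptp(record.x[s.sl])) for s in ss], starts)
        _agg_into(out, f"{inf}:SHEIGHT",
                  [float(np.ptp(record.y[s.sl])) for s in ss], starts)
        _agg_into(out, f"{inf}:SLEN",
                  [polyline_length(_stroke_points(record, s)) for s in ss],
                  starts)
    return out


# --------------------------------------------------------------- kinematic


def _velocity_series(
    record: HandwritingRecord, strokes: list[Stroke], kind: str,
    projection: str,
):
    """Per-sample speed series within strokes of one class, concatenated.

    Returns (vel, t_vel, acc, t_acc, avel, t_avel); angular velocity is
    only defined for the full xy projection (direction of motion angle,
    unwrapped, differentiated).
    """
    fs = record.fs
    vel, tv, acc, ta, avel, tav = [], [], [], [], [], []
    for s in strokes_of(strokes, kind):
        if s.n_samples < 2:
            continue
        vx = np.diff(record.x[s.sl]) * fs
        vy = np.diff(record.y[s.sl]) * fs
        tt = record.t[s.start_index : s.end_index]  # left edges
        if projection == "xy":
            v = np.hypot(vx, vy)
        elif projection == "h":
            v = np.abs(vx)
        elif projection == "v":
            v = np.abs(vy)
        else:
            raise ValueError(f"unknown projection {projection!r}")
        vel.append(v)
        tv.append(tt)
        if s.n_samples >= 3:
            acc.append(np.diff(v) * fs)
            ta.append(tt[:-1])
            if projection == "xy":
                phi = np.unwrap(np.arctan2(vy, vx))
                avel.append(np.diff(phi) * fs)
                tav.append(tt[:-1])

    def cat(parts):
        return np.concatenate(parts) if parts else np.array([])

    return cat(vel), cat(tv), cat(acc), cat(ta), cat(avel), cat(tav)


def kinematic_features(
    record: HandwritingRecord, strokes: list[Stroke]
) -> dict[str, float]:
    out: dict[str, float] = {}
    for inf, kind in _CLASSES:
        for proj, tag in (("xy", ""), ("h", "H-"), ("v", "V-")):
            vel, tv, acc, ta, avel, tav = _velocity_series(
                record, strokes, kind, proj
            )
            _agg_into(out, f"{inf}:{tag}VEL", vel, tv, KINEMATIC_STATS)
            _agg_into(out, f"{inf}:{tag}ACC", acc, ta, KINEMATIC_STATS)
            if proj == "xy":
                _agg_into(out, f"{inf}:AVEL", avel, tav, KINEMATIC_STATS)
    return out


# ----------------------------------------------------------------- dynamic


def dynamic_features(
    record: HandwritingRecord, strokes: list[Stroke]
) -> tuple[dict[str, float], list[str]]:
    out: dict[str, float] = {}
    qc: list[str] = []
    on = record.b == 1
    if np.any(on) and np.any(record.p[on] != 0):
        _agg_into(out, "PRESS", record.p[on], record.t[on])
    else:
        _agg_into(out, "PRESS", [])
        qc.append("pressure channel all-zero on-surface; sensor absent")
    _agg_into(out, "TILT", record.tilt, record.t)
    _agg_into(out, "AZIM", record.azimuth, record.t)
    return out, qc


# ------------------------------------------------------------ event counts


def _count_extrema(series: np.ndarray) -> int:
    """Local extrema = sign changes of the first difference, ignoring
    zero-difference plateaus."""
    d = np.diff(np.asarray(series, float))
    s = np.sign(d)
    s = s[s != 0]
    if len(s) < 2:
        return 0
    return int(np.count_nonzero(np.diff(s) != 0))


def profile_change_counts(
    record: HandwritingRecord, strokes: list[Stroke]
) -> dict[str, float]:
    on_dur = sum(s.duration(record) for s in strokes_of(strokes, "on_surface"))
    if on_dur <= 0:
        return {k: np.nan for k in ("RNCV", "RNCP", "RNCT", "RNCA")}
    vel, *_ = _velocity_series(record, strokes, "on_surface", "xy")
    on = record.b == 1
    return {
        "RNCV": _count_extrema(vel) / on_dur,
        "RNCP": _count_extrema(record.p[on]) / on_dur,
        "RNCT": _count_extrema(record.tilt) / on_dur,
        "RNCA": _count_extrema(record.azimuth) / on_dur,
    }


def interruption_features(
    record: HandwritingRecord, strokes: list[Stroke]
) -> dict[str, float]:
    """Pen elevations: in-air strokes flanked by on-surface strokes."""
    nint = sum(
        1
        for prev, cur, nxt in zip(strokes, strokes[1:], strokes[2:])
        if cur.kind == "in_air"
        and prev.kind == "on_surface"
        and nxt.kind == "on_surface"
    )
    total = record.duration
    return {"NINT": float(nint), "RNINT": nint / total if total > 0 else np.nan}


def intersection_features(
    record: HandwritingRecord, strokes: list[Stroke]
) -> dict[str, float]:
    on = strokes_of(strokes, "on_surface")
    pts = [_stroke_points(record, s) for s in on]
    niei = sum(
        count_polyline_intersections(pts[i], pts[j])
        for i in range(len(pts))
        for j in range(i + 1, len(pts))
    )
    self_counts = [
        count_polyline_intersections(p, self_mode=True) for p in pts
    ]
    tniai = float(sum(self_counts))
    niai = float(np.median(self_counts)) if self_counts else np.nan
    length = sum(polyline_length(p) for p in pts)
    rel = (lambda c: c / length) if length > 0 else (lambda c: np.nan)
    return {
        "NIEI": float(niei), "RNIEI": rel(niei),
        "NIAI": niai, "RNIAI": rel(niai) if self_counts else np.nan,
        "TNIAI": tniai, "RTNIAI": rel(tniai),
    }


# ------------------------------------------------------------ full battery


def extract_feature_vector(
    record: HandwritingRecord, strokes: list[Stroke] | None = None
) -> FeatureVector:
    """Compute the full battery for one preprocessed record.

    The spiral-specific family is included only for the spiral task.
    Feature order is deterministic; undefined values are NaN and listed
    in the vector's QC report.
    """
    if strokes is None:
        strokes = segment_strokes(record)
    qc: list[str] = []
    values: dict[str, float] = {}
    values.update(temporal_features(record, strokes))
    values.update(spatial_features(record, strokes))
    values.update(kinematic_features(record, strokes))
    dyn, dyn_qc = dynamic_features(record, strokes)
    values.update(dyn)
    qc.extend(dyn_qc)
    if record.meta.task == "spiral":
        sp, sp_qc = spiral_features(record, strokes)
        values.update(sp)
        qc.extend(sp_qc)
    values.update(interruption_features(record, strokes))
    values.update(intersection_features(record, strokes))
    values.update(profile_change_counts(record, strokes))
    qc.extend(
        f"missing: {name}" for name, v in values.items() if not np.isfinite(v)
    )
    return FeatureVector(
        values=values, task=record.meta.task,
        subject_id=record.meta.subject_id, qc=qc,
    )


def feature_names(task: str) -> list[str]:
    """Canonical feature order for a task (schema of the feature table)."""
    import warnings

    from .records import SubjectMeta

    rng = np.random.default_rng(0)
    n = 400
    t = np.arange(n) / 133.0
    theta = np.linspace(0.5, 6 * np.pi, n)
    b = np.ones(n)
    b[150:170] = 0.0
    b[300:315] = 0.0
    rec = HandwritingRecord(
        x=2 * theta * np.cos(theta) + 0.01 * rng.standard_normal(n),
        y=2 * theta * np.sin(theta) + 0.01 * rng.standard_normal(n),
        t=t, b=b, p=np.where(b == 1, 500.0, 0.0),
        tilt=60 + rng.standard_normal(n).cumsum() * 0.01,
        azimuth=180 + rng.standard_normal(n).cumsum() * 0.01,
        fs=133.0, meta=SubjectMeta(task=task),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return extract_feature_vector(rec).names()
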