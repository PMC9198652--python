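"""The handcrafted feature battery: family-level checks and invariances."""

import numpy as np
import pytest

from graphomotor.features import (
    dynamic_features,
    extract_feature_vector,
    interruption_features,
    intersection_features,
    kinematic_features,
    profile_change_counts,
    spatial_features,
    temporal_features,
)
from graphomotor.records import segment_strokes


def _strokes(rec, min_samples=2):
    return segment_strokes(rec, min_samples=min_samples)


class TestTemporal:
    def test_durations_and_ratio(self, make_record):
        # 1 s on, 1 s air, 1 s on at 10 Hz
        b = [1] * 10 + [0] * 10 + [1] * 10
        n = len(b)
        rec = make_record(np.arange(n), np.zeros(n), fs=10.0, b=b)
        out = temporal_features(rec, _strokes(rec))
        assert out["ON:DUR"] == pytest.approx(2.0)
        assert out["AIR:DUR"] == pytest.approx(1.0)
        assert out["DURR"] == pytest.approx(2.0)

    def test_single_stroke_ratio_missing(self, make_record):
        rec = make_record(np.arange(5), np.zeros(5))
        out = temporal_features(rec, _strokes(rec))
        assert np.isnan(out["DURR"])
        assert np.isnan(out["AIR:DUR"])

    def test_stroke_duration_aggregates(self, make_record):
        # three 0.5 s on-strokes separated by 0.5 s air gaps at 10 Hz
        b = ([1] * 5 + [0] * 5) * 2 + [1] * 5
        n = len(b)
        rec = make_record(np.arange(n), np.zeros(n), fs=10.0, b=b)
        out = temporal_features(rec, _strokes(rec))
        assert out["ON:SDUR(median)"] == pytest.approx(0.5)
        assert out["ON:SDUR(iqr)"] == pytest.approx(0.0)
        # pairwise on/air ratios: 0.5/0.5 twice
        assert out["SDURR(median)"] == pytest.approx(1.0)


class TestSpatial:
    def test_square_path(self, make_record):
        square = np.array(
            [[0, 0], [10, 0], [10, 10], [0, 10], [0, 0]], dtype=float
        )
        rec = make_record(square[:, 0], square[:, 1], fs=10.0)
        out = spatial_features(rec, _strokes(rec))
        assert out["ON:WIDTH"] == pytest.approx(10.0)
        assert out["ON:HEIGHT"] == pytest.approx(10.0)
        assert out["ON:LEN"] == pytest.approx(40.0)

    def test_stationary_stroke_zero_length(self, make_record):
        rec = make_record([1.0, 1.0], [2.0, 2.0], fs=10.0)
        out = spatial_features(rec, _strokes(rec))
        assert out["ON:SLEN(median)"] == 0.0

    def test_two_parallel_strokes(self, make_record):
        x = np.concatenate([np.linspace(0, 10, 6), np.linspace(10, 0, 3),
                            np.linspace(0, 10, 6)])
        y = np.concatenate([np.zeros(6), np.linspace(0, 5, 3), np.full(6, 5.0)])
        b = [1] * 6 + [0] * 3 + [1] * 6
        rec = make_record(x, y, b=b, fs=10.0)
        out = spatial_features(rec, _strokes(rec))
        assert out["ON:SLEN(median)"] == pytest.approx(10.0)
        assert out["ON:LEN"] == pytest.approx(20.0)


class TestKinematic:
    def test_straight_line_velocity(self, make_record):
        t = np.arange(200) / 100.0
        rec = make_record(10.0 * t, np.zeros_like(t), t=t, fs=100.0)
        out = kinematic_features(rec, _strokes(rec))
        assert out["ON:VEL(median)"] == pytest.approx(10.0)
        assert out["ON:ACC(median)"] == pytest.approx(0.0, abs=1e-9)
        assert out["ON:H-VEL(median)"] == pytest.approx(10.0)

    def test_circle_angular_velocity(self, make_record):
        fs, omega, radius = 133.0, 2.0, 10.0
        t = np.arange(int(2 * 2 * np.pi / omega * fs)) / fs
        rec = make_record(radius * np.cos(omega * t),
                          radius * np.sin(omega * t), t=t, fs=fs,
                          task="sentence")
        out = kinematic_features(rec, _strokes(rec))
        assert out["ON:AVEL(median)"] == pytest.approx(omega, rel=0.01)
        assert out["ON:VEL(median)"] == pytest.approx(radius * omega, rel=0.01)

    def test_vertical_motion_has_zero_horizontal_speed(self, make_record):
        t = np.arange(100) / 100.0
        rec = make_record(np.zeros_like(t), 5.0 * t, t=t, fs=100.0)
        out = kinematic_features(rec, _strokes(rec))
        assert out["ON:H-VEL(median)"] == pytest.approx(0.0, abs=1e-12)
        assert out["ON:V-VEL(median)"] == pytest.approx(5.0)


class TestDynamic:
    def test_constant_pressure(self, make_record):
        rec = make_record(np.arange(10), np.zeros(10),
                          p=np.full(10, 512.0), fs=10.0)
        out, qc = dynamic_features(rec, _strokes(rec))
        assert out["PRESS(median)"] == 512.0
        assert out["PRESS(iqr)"] == 0.0
        assert qc == []

    def test_azimuth_sweep_slope(self, make_record):
        t = np.arange(91) / 10.0  # 9 s
        rec = make_record(np.arange(91), np.zeros(91), t=t, fs=10.0,
                          azimuth=np.linspace(0, 90, 91))
        out, _ = dynamic_features(rec, _strokes(rec))
        assert out["AZIM(slope)"] == pytest.approx(10.0)

    def test_zero_pressure_flagged_missing(self, make_record):
        rec = make_record(np.arange(10), np.zeros(10), p=np.zeros(10), fs=10.0)
        out, qc = dynamic_features(rec, _strokes(rec))
        assert np.isnan(out["PRESS(median)"])
        assert any("pressure" in w for w in qc)


class TestEventCounts:
    def test_monotone_velocity_no_changes(self, make_record):
        t = np.arange(100) / 100.0
        rec = make_record(t**2, np.zeros_like(t), t=t, fs=100.0)
        out = profile_change_counts(rec, _strokes(rec))
        assert out["RNCV"] == 0.0
        assert out["RNCP"] == 0.0

    def test_sinusoidal_velocity_extrema_rate(self, make_record):
        # speed 1 + sin(2*pi*5t) over 2 s: 20 extrema -> ~10 per second
        fs = 133.0
        t = np.arange(int(2 * fs) + 1) / fs
        v = 1.0 + np.sin(2 * np.pi * 5.0 * t)
        x = np.concatenate(([0.0], np.cumsum(v[:-1] / fs)))
        rec = make_record(x, np.zeros_like(t), t=t, fs=fs)
        out = profile_change_counts(rec, _strokes(rec))
        assert out["RNCV"] == pytest.approx(10.0, abs=0.6)

    def test_interruptions(self, make_record):
        rec = make_record(np.arange(6), np.zeros(6), b=[1, 1, 0, 0, 1, 1],
                          fs=10.0)
        out = interruption_features(rec, _strokes(rec))
        assert out["NINT"] == 1

    def test_no_interruptions_single_stroke(self, make_record):
        rec = make_record(np.arange(5), np.zeros(5), fs=10.0)
        out = interruption_features(rec, _strokes(rec))
        assert out["NINT"] == 0
        assert out["RNINT"] == 0

    def test_interruption_rate(self, make_record):
        # 3 on-strokes and 2 enclosed air gaps over 10 s at 10 Hz
        b = [1] * 21 + [0] * 20 + [1] * 20 + [0] * 20 + [1] * 20
        n = len(b)
        rec = make_record(np.arange(n), np.zeros(n), fs=10.0, b=b)
        out = interruption_features(rec, _strokes(rec))
        assert out["NINT"] == 2
        assert out["RNINT"] == pytest.approx(2 / rec.duration)


class TestIntersections:
    def test_two_crossing_strokes(self, make_record):
        x = [0, 10, 5, 5, 5]
        y = [5, 5, 5, 0, 10]
        b = [1, 1, 0, 1, 1]
        rec = make_record(x, y, b=b, fs=10.0)
        out = intersection_features(rec, _strokes(rec, min_samples=1))
        assert out["NIEI"] == 1
        assert out["TNIAI"] == 0

    def test_figure_eight_stroke(self, make_record):
        pts = np.array([[0, 0], [2, 2], [2, 0], [0, 2], [0, 0]], float)
        rec = make_record(pts[:, 0], pts[:, 1], fs=10.0)
        out = intersection_features(rec, _strokes(rec))
        assert out["NIAI"] == 1
        assert out["TNIAI"] == 1
        assert out["NIEI"] == 0

    def test_grid_of_strokes(self, make_record):
        # 3 horizontal + 3 vertical full-width strokes: 9 crossings
        xs, ys, bs = [], [], []
        for k, yy in enumerate([2.0, 5.0, 8.0]):
            xs += [0.0, 10.0, 10.0]
            ys += [yy, yy, yy]
            bs += [1, 1, 0]
        for k, xx in enumerate([2.0, 5.0, 8.0]):
            xs += [xx, xx, xx]
            ys += [0.0, 10.0, 10.0]
            bs += [1, 1, 0]
        rec = make_record(xs, ys, b=bs, fs=10.0)
        out = intersection_features(rec, _strokes(rec, min_samples=1))
        assert out["NIEI"] == 9


class TestFullVector:
    def test_spiral_schema(self, ideal_spiral_record):
        fv = extract_feature_vector(ideal_spiral_record)
        names = fv.names()
        for expected in ("ON:VEL(95p)", "AIR:SDUR(iqr)", "TGHTNS", "RNCV",
                         "DURR", "PRESS(median)", "NINT"):
            assert expected in names
        assert len(names) == len(set(names))

    def test_sentence_has_no_spiral_family(self, make_record):
        t = np.arange(50) / 100.0
        rec = make_record(10 * t, np.sin(t), t=t, task="sentence")
        fv = extract_feature_vector(rec)
        assert "TGHTNS" not in fv.values
        assert "SPI" not in fv.values

    def test_deterministic(self, ideal_spiral_record):
        a = extract_feature_vector(ideal_spiral_record)
        b = extract_feature_vector(ideal_spiral_record)
        assert a.values == b.values

    def test_ncv_identity(self, ideal_spiral_record):
        fv = extract_feature_vector(ideal_spiral_record)
        for name, v in fv.values.items():
            if name.endswith("(ncv)") and np.isfinite(v):
                med = fv.values[name.replace("(ncv)", "(median)")]
                iqr = fv.values[name.replace("(ncv)", "(iqr)")]
                assert v == pytest.approx(iqr / med)


@pytest.fixture(scope="module")
def spiral_pair():
    from graphomotor.simulate import EffectProfile, simulate_spiral

    # pen lifts and mild tremor so strokes, interruptions and spiral
    # residuals are all exercised; no jitter so transforms are exact
    profile = EffectProfile(jitter_sd=0.0, tremor_amp=0.5,
                            extra_lift_rate=0.3)
    return simulate_spiral(profile, seed=12)


class TestInvariances:
    def test_scale_equivariance(self, spiral_pair):
        rec = spiral_pair
        k = 2.5
        scaled = rec.copy_with(x=rec.x * k, y=rec.y * k)
        a = extract_feature_vector(rec).values
        b = extract_feature_vector(scaled).values
        for name in ("ON:WIDTH", "ON:HEIGHT", "ON:LEN", "ON:VEL(median)",
                     "ON:ACC(95p)", "MDS", "TGHTNS"):
            assert b[name] == pytest.approx(k * a[name], rel=1e-6)
        for name in ("DURR", "NINT", "DoS", "SPI", "1stZC", "RNCV"):
            assert b[name] == pytest.approx(a[name], rel=1e-6, abs=1e-12)

    def test_time_dilation(self, spiral_pair):
        rec = spiral_pair
        k = 2.0
        slow = rec.copy_with(t=rec.t * k, fs=rec.fs / k)
        a = extract_feature_vector(rec).values
        b = extract_feature_vector(slow).values
        assert b["ON:VEL(median)"] == pytest.approx(
            a["ON:VEL(median)"] / k, rel=1e-6
        )
        assert b["ON:ACC(95p)"] == pytest.approx(
            a["ON:ACC(95p)"] / k**2, rel=1e-6
        )
        assert b["ON:DUR"] == pytest.approx(k * a["ON:DUR"], rel=1e-9)
        for name in ("ON:WIDTH", "ON:HEIGHT", "ON:LEN"):
            assert b[name] == pytest.approx(a[name], rel=1e-9)

    def test_rotation_invariance(self, spiral_pair):
        rec = spiral_pair
        ang = 0.7
        c, s = np.cos(ang), np.sin(ang)
        rot = rec.copy_with(x=c * rec.x - s * rec.y, y=s * rec.x + c * rec.y)
        a = extract_feature_vector(rec).values
        b = extract_feature_vector(rot).values
        for name in ("ON:VEL(median)", "ON:LEN", "DoS", "SPI", "TGHTNS",
                     "1stSm"):
            assert b[name] == pytest.approx(a[name], rel=1e-5, abs=1e-9)
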