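import numpy as np
import pytest

from graphomotor.records import HandwritingRecord, SubjectMeta


@pytest.fixture
def make_record():
    """Factory for records with sensible channel defaults."""

    def _make(
        x,
        y,
        t=None,
        b=None,
        p=None,
        tilt=None,
        azimuth=None,
        fs=None,
        task="sentence",
        label="HC",
        language="CZ",
        subject_id="s01",
    ):
        x = np.asarray(x, dtype=float)
        n = len(x)
        if t is None:
            fs = fs or 100.0
            t = np.arange(n) / fs
        else:
            t = np.asarray(t, dtype=float)
            fs = fs or float(1.0 / np.median(np.diff(t)))
        b = np.ones(n) if b is None else np.asarray(b, dtype=float)
        p = np.where(b == 1, 500.0, 0.0) if p is None else np.asarray(p, float)
        tilt = np.full(n, 60.0) if tilt is None else np.asarray(tilt, float)
        azimuth = (
            np.full(n, 200.0) if azimuth is None else np.asarray(azimuth, float)
        )
        meta = SubjectMeta(
            subject_id=subject_id, label=label, language=language, task=task
        )
        return HandwritingRecord(
            x=x, y=np.asarray(y, dtype=float), t=t, b=b, p=p, tilt=tilt,
            azimuth=azimuth, fs=fs, meta=meta,
        )

    return _make


def ideal_spiral_arrays(c1=2.0, revolutions=3.0, speed=30.0, fs=133.0,
                        theta0=1e-3):
    """Archimedean spiral r = c1*theta traversed at constant speed."""
    theta = np.linspace(theta0, 2 * np.pi * revolutions, 8000)
    ds = c1 * np.sqrt(1 + theta**2)
    s = np.concatenate(
        ([0.0], np.cumsum((ds[1:] + ds[:-1]) / 2 * np.diff(theta)))
    )
    t = np.arange(int(s[-1] / speed * fs)) / fs
    th = np.interp(speed * t, s, theta)
    r = c1 * th
    return r * np.cos(th), r * np.sin(th), t


@pytest.fixture
def ideal_spiral_record(make_record):
    x, y, t = ideal_spiral_arrays()
    return make_record(x, y, t=t, fs=133.0, task="spiral")
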