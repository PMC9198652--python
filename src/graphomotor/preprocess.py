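"""Unit unification and resampling of pen recordings.

Tablets report position in device counts and time in device ticks;
analysis requires millimetres and seconds on a uniform time grid shared
by all devices (133 Hz by default, the native rate of ink-on-paper
tablet setups; display tablets record at 180 Hz and are resampled
down).

Resampling low-pass filters the continuous channels with a windowed-sinc
FIR antialiasing filter applied zero-phase, then interpolates linearly
onto the uniform grid.  The binary pen-state channel is never filtered:
it is resampled by zero-order hold so it stays in {0, 1}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .records import HandwritingRecord

__all__ = ["DeviceProfile", "normalize_units", "to_uniform_rate"]

TARGET_FS = 133.0


@dataclass(frozen=True)
class DeviceProfile:
    """Conversion factors from device units to mm and seconds.

    counts_per_mm : position counts reported per millimetre
    ticks_per_second : timestamp ticks per second
    """

    counts_per_mm: float = 1.0
    ticks_per_second: float = 1.0

    def __post_init__(self) -> None:
        if self.counts_per_mm <= 0 or self.ticks_per_second <= 0:
            raise ValueError("device profile scale factors must be positive")


def normalize_units(
    record: HandwritingRecord, profile: DeviceProfile = DeviceProfile()
) -> HandwritingRecord:
    """Express x/y in millimetres and t in seconds starting at zero.

    Pressure, tilt and azimuth stay in their (dimensionless) device
    ranges.
    """
    t = (record.t - record.t[0]) / profile.ticks_per_second
    return record.copy_with(
        x=record.x / profile.counts_per_mm,
        y=record.y / profile.counts_per_mm,
        t=t,
        fs=record.fs * profile.ticks_per_second,
    )


def _fir_lowpass(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    """Zero-phase windowed-sinc low-pass; falls back to identity when the
    record is shorter than the filter warm-up."""
    numtaps = 101
    if len(x) <= 3 * numtaps:
        numtaps = max(3, 2 * (len(x) // 6) + 1)
    if numtaps < 9 or cutoff >= fs / 2:
        return x
    taps = signal.firwin(numtaps, cutoff, fs=fs)
    return signal.filtfilt(taps, [1.0], x, padtype="even")


def to_uniform_rate(
    record: HandwritingRecord, target_fs: float = TARGET_FS
) -> HandwritingRecord:
    """Resample a unit-normalised record onto the uniform grid k/target_fs.

    Continuous channels (x, y, p, tilt, azimuth) are antialias-filtered
    below the target Nyquist (cutoff 0.45 * target_fs) and linearly
    interpolated; the pen state b is held (previous-sample) so it stays
    binary.  The output spans [t0, t_end] with
    ``floor((t_end - t0) * target_fs) + 1`` samples.

    Timestamps may be non-uniform: channels are first linearly gridded
    at the source nominal rate, because FIR filtering assumes uniform
    sampling.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")

    t0, t_end = float(record.t[0]), float(record.t[-1])
    src_fs = record.fs
    # grid at the source nominal rate (no-op when already uniform)
    n_src = int(np.floor((t_end - t0) * src_fs)) + 1
    t_src = t0 + np.arange(n_src) / src_fs

    n_out = int(np.floor((t_end - t0) * target_fs)) + 1
    t_out = t0 + np.arange(n_out) / target_fs

    cutoff = 0.45 * target_fs
    out: dict[str, np.ndarray] = {}
    for name in ("x", "y", "p", "tilt", "azimuth"):
        ch = np.interp(t_src, record.t, getattr(record, name))
        if src_fs > 2 * cutoff:
            if n_src < 30:
                warnings.warn(
                    "record shorter than filter warm-up; "
                    "falling back to plain linear interpolation"
                )
            else:
                ch = _fir_lowpass(ch, src_fs, cutoff)
        out[name] = np.interp(t_out, t_src, ch)

    # pen state: previous-sample hold on the original timestamps
    idx = np.searchsorted(record.t, t_out, side="right") - 1
    out["b"] = record.b[np.clip(idx, 0, len(record.b) - 1)]

    return record.copy_with(t=t_out, fs=float(target_fs), **out)
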