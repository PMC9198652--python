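"""Core in-memory containers for online handwriting recordings.

A recording is the multichannel time series produced by a digitizing
tablet: pen position (x, y), a timestamp, the binary pen state (1 while
the tip touches the surface, 0 while it hovers in air), the axial
pressure, and the two pen-orientation angles (tilt and azimuth).
Strokes are maximal runs of constant pen state; they tile the recording
without gaps or overlap and alternate between on-surface and in-air.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "SubjectMeta",
    "HandwritingRecord",
    "Stroke",
    "segment_strokes",
]

Label = Literal["PD", "HC"]
Task = Literal["spiral", "sentence"]

LANGUAGES = ("CZ", "CO", "HU", "US")


@dataclass(frozen=True)
class SubjectMeta:
    """Identity and acquisition metadata for one recording.

    One recording exists per (subject, task): every classification
    decision downstream is per subject.
    """

    subject_id: str = ""
    label: str = "HC"
    language: str = "CZ"
    task: str = "spiral"
    device: str = "synthetic"


@dataclass
class HandwritingRecord:
    """Multichannel pen time series.

    Channels (equal length, >= 2 samples):

    x, y : pen position; millimetres after unit normalisation
    t : timestamps in seconds, strictly increasing
    b : binary pen state, 1 on-surface / 0 in-air
    p : axial pressure in device units (0 while in air)
    tilt, azimuth : pen orientation angles, degrees
    fs : nominal sampling rate in Hz
    """

    x: np.ndarray
    y: np.ndarray
    t: np.ndarray
    b: np.ndarray
    p: np.ndarray
    tilt: np.ndarray
    azimuth: np.ndarray
    fs: float
    meta: SubjectMeta = field(default_factory=SubjectMeta)

    CHANNELS = ("x", "y", "t", "b", "p", "tilt", "azimuth")

    def __post_init__(self) -> None:
        for name in self.CHANNELS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    def validate(self) -> None:
        n = len(self.t)
        if n < 2:
            raise ValueError("record needs at least 2 samples")
        for name in self.CHANNELS:
            if len(getattr(self, name)) != n:
                raise ValueError(
                    f"channel {name!r} has length {len(getattr(self, name))}, expected {n}"
                )
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isin(self.b, (0.0, 1.0))):
            raise ValueError("pen state channel b must be binary (0/1)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def copy_with(self, **channels) -> "HandwritingRecord":
        return replace(self, **channels)


@dataclass(frozen=True)
class Stroke:
    """Maximal run of constant pen state, as an inclusive index slice."""

    kind: Literal["on_surface", "in_air"]
    start_index: int
    end_index: int
    record_ref: str = ""

    def __post_init__(self) -> None:
        if self.start_index > self.end_index:
            raise ValueError("start_index must be <= end_index")

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index + 1

    @property
    def sl(self) -> slice:
        return slice(self.start_index, self.end_index + 1)

    def duration(self, record: HandwritingRecord) -> float:
        """Stroke duration with each sample owning one sampling interval,
        so stroke durations tile the record's total n/fs exactly."""
        return self.n_samples / record.fs


def segment_strokes(
    record: HandwritingRecord, min_samples: int = 2
) -> list[Stroke]:
    """Split a record into alternating on-surface / in-air strokes.

    Runs shorter than ``min_samples`` are treated as digitizer glitches
    (single-sample pen bounces) and merged into the preceding stroke;
    the leading run is always kept regardless of its length.  The
    returned strokes tile the record exactly and alternate kind.
    """
    b = record.b.astype(int)
    # boundaries where pen state flips
    change = np.flatnonzero(np.diff(b) != 0) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change - 1, [len(b) - 1]))

    runs: list[list[int]] = []  # [start, end, state]
    for s, e in zip(starts, ends):
        state = b[s]
        if runs and (e - s + 1) < min_samples:
            runs[-1][1] = e  # glitch: absorb into preceding stroke
        elif runs and runs[-1][2] == state:
            runs[-1][1] = e  # re-merge after an absorbed glitch
        else:
            runs.append([s, e, state])

    ref = record.meta.subject_id
    return [
        Stroke(
            kind="on_surface" if state else "in_air",
            start_index=s,
            end_index=e,
            record_ref=ref,
        )
        for s, e, state in runs
    ]


def strokes_of(strokes: Sequence[Stroke], kind: str) -> list[Stroke]:
    """Filter strokes by kind ('on_surface' or 'in_air')."""
    return [s for s in strokes if s.kind == kind]
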