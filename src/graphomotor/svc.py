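"""Reading and writing SVC-style plain-text pen recordings.

The SVC family of formats stores one sample per line as whitespace
separated numeric columns.  Column order differs between exporters, so
it is explicit here via :class:`SvcDialect`; the default matches a
common Wacom export order ``x y t b azimuth tilt p``.

A cohort on disk is described by a manifest CSV with columns
``subject_id, label, language, task, path``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .records import HandwritingRecord, SubjectMeta

__all__ = ["SvcDialect", "SvcParseError", "read_svc", "write_svc",
           "read_manifest", "write_manifest"]

_CHANNELS = ("x", "y", "t", "b", "azimuth", "tilt", "p")


@dataclass(frozen=True)
class SvcDialect:
    """Column order of an SVC file; every channel must appear once."""

    columns: tuple[str, ...] = _CHANNELS

    def __post_init__(self) -> None:
        if sorted(self.columns) != sorted(_CHANNELS):
            raise ValueError(
                f"dialect must be a permutation of {_CHANNELS}, got {self.columns}"
            )


DEFAULT_DIALECT = SvcDialect()


class SvcParseError(ValueError):
    """Raised for malformed SVC content, carrying the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


def read_svc(
    path: str | Path,
    dialect: SvcDialect = DEFAULT_DIALECT,
    meta: SubjectMeta | None = None,
    fs: float | None = None,
) -> HandwritingRecord:
    """Read one SVC file into a :class:`HandwritingRecord`.

    Raw device units are preserved.  The sampling rate is ``fs`` if
    given, else the median of 1/dt.  Timestamps must be strictly
    increasing and at least two samples are required.
    """
    ncol = len(dialect.columns)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != ncol:
                raise SvcParseError(
                    f"expected {ncol} columns, got {len(parts)}", lineno
                )
            try:
                rows.append([float(v) for v in parts])
            except ValueError as exc:
                raise SvcParseError(str(exc), lineno) from exc
    if len(rows) < 2:
        raise SvcParseError(f"file {path} has {len(rows)} samples; need >= 2")

    data = np.asarray(rows, dtype=float)
    channels = {name: data[:, i] for i, name in enumerate(dialect.columns)}
    t = channels["t"]
    if np.any(np.diff(t) <= 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 2
        raise SvcParseError("timestamps not strictly increasing", bad)
    if fs is None:
        fs = float(1.0 / np.median(np.diff(t)))
    return HandwritingRecord(
        x=channels["x"], y=channels["y"], t=t, b=channels["b"],
        p=channels["p"], tilt=channels["tilt"], azimuth=channels["azimuth"],
        fs=fs, meta=meta or SubjectMeta(),
    )


def write_svc(
    record: HandwritingRecord,
    path: str | Path,
    dialect: SvcDialect = DEFAULT_DIALECT,
    fmt: str = "%.6f",
) -> None:
    """Write a record as SVC text; round-trips bit-stably at ``fmt`` precision."""
    cols = [getattr(record, name) for name in dialect.columns]
    data = np.column_stack(cols)
    np.savetxt(path, data, fmt=fmt)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV (subject_id, label, language, task, path)."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "label", "language", "task", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def load_cohort(
    manifest: str | Path | pd.DataFrame,
    dialect: SvcDialect = DEFAULT_DIALECT,
    root: str | Path | None = None,
) -> list[HandwritingRecord]:
    """Load every record listed in a manifest."""
    df = manifest if isinstance(manifest, pd.DataFrame) else read_manifest(manifest)
    records = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if root is not None and not p.is_absolute():
            p = Path(root) / p
        meta = SubjectMeta(
            subject_id=str(row.subject_id), label=row.label,
            language=row.language, task=row.task,
        )
        records.append(read_svc(p, dialect=dialect, meta=meta))
    return records
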