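"""Synthetic multilingual PD/HC handwriting cohorts.

Every pipeline stage is testable without clinical data through a
generator that emulates the motor signature of parkinsonian writing on
a digitizing tablet:

* bradykinesia — reduced pen speed (``velocity_scale`` < 1)
* action tremor — a radial/vertical oscillation in the classic 4-7 Hz
  parkinsonian band (``tremor_amp``, ``tremor_freq``)
* micrographia — per-revolution (spiral) or per-stroke (sentence)
  amplitude shrinkage (``amplitude_decay``)
* hypotonia — reduced axial pen pressure (``pressure_scale``)
* dysfluency — extra pen lifts inserted as a Poisson process
  (``extra_lift_rate``)
* motor noise — Gaussian positional jitter (``jitter_sd``)

The class signal is injected *only* through the PD effect profile;
language acts purely as a nuisance style (stroke counts, letter height,
slant) applied to both groups, mirroring the fact that a spiral drawing
is language-independent while sentences differ in orthography.  A
``null_mode`` profile makes the PD and HC generating distributions
identical, for chance-level calibration.

All randomness flows from one root seed through per-subject
``numpy.random.SeedSequence`` spawning, so cohorts of any size are
reproducible sample-for-sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .records import HandwritingRecord, SubjectMeta
from .svc import write_manifest, write_svc

__all__ = [
    "EffectProfile",
    "LanguageStyle",
    "CohortConfig",
    "NEUTRAL_PROFILE",
    "DEFAULT_STYLES",
    "simulate_spiral",
    "simulate_sentence",
    "simulate_cohort",
]


@dataclass(frozen=True)
class EffectProfile:
    """Tunable deficit sizes for the PD group (HC uses the neutral profile).

    velocity_scale : multiplicative factor on mean pen speed (PD < 1)
    tremor_amp : tremor oscillation amplitude, mm
    tremor_freq : tremor frequency, Hz (parkinsonian band 4-7)
    amplitude_decay : fractional shrink per revolution / per stroke
    pressure_scale : multiplicative factor on axial pressure
    extra_lift_rate : added pen lifts per second (Poisson rate)
    jitter_sd : isotropic positional noise, mm
    null_mode : force every factor to its neutral value
    """

    velocity_scale: float = 1.0
    tremor_amp: float = 0.0
    tremor_freq: float = 5.0
    amplitude_decay: float = 0.0
    pressure_scale: float = 1.0
    extra_lift_rate: float = 0.0
    jitter_sd: float = 0.05
    null_mode: bool = False

    def __post_init__(self) -> None:
        if self.velocity_scale <= 0 or self.pressure_scale <= 0:
            raise ValueError("scale factors must be positive")
        if not 0 <= self.amplitude_decay < 1:
            raise ValueError("amplitude_decay must be in [0, 1)")
        if min(self.tremor_amp, self.tremor_freq, self.extra_lift_rate,
               self.jitter_sd) < 0:
            raise ValueError("amplitudes and rates must be non-negative")

    def resolve(self) -> "EffectProfile":
        """The profile actually applied: neutral when null_mode is set."""
        if self.null_mode:
            return replace(
                NEUTRAL_PROFILE, jitter_sd=self.jitter_sd, null_mode=True
            )
        return self


NEUTRAL_PROFILE = EffectProfile()

# PD effect sizes used as the cohort default: moderate bradykinesia
# (speed down 40%), 1 mm tremor at 5 Hz, mild micrographia, reduced
# pressure, about one extra lift every 2.5 s.
PD_PROFILE = EffectProfile(
    velocity_scale=0.6,
    tremor_amp=1.0,
    tremor_freq=5.0,
    amplitude_decay=0.02,
    pressure_scale=0.8,
    extra_lift_rate=0.4,
)


@dataclass(frozen=True)
class LanguageStyle:
    """Language-level nuisance style, shared by PD and HC subjects."""

    stroke_count_range: tuple[int, int] = (15, 40)
    letter_height_mm: float = 8.0
    slant_deg: float = 0.0


DEFAULT_STYLES: dict[str, LanguageStyle] = {
    "CZ": LanguageStyle((18, 34), 8.0, 2.0),
    "CO": LanguageStyle((22, 40), 9.0, -3.0),
    "HU": LanguageStyle((20, 38), 7.0, 5.0),
    "US": LanguageStyle((15, 30), 10.0, 0.0),
}


@dataclass(frozen=True)
class CohortConfig:
    """Composition and effect sizes of a synthetic cohort."""

    n_per_group_per_language: int = 30
    languages: tuple[str, ...] = ("CZ", "CO", "HU", "US")
    task: str = "spiral"
    effects: EffectProfile = PD_PROFILE
    language_styles: dict[str, LanguageStyle] = field(
        default_factory=lambda: dict(DEFAULT_STYLES)
    )
    fs: float = 133.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group_per_language < 1:
            raise ValueError("need at least one subject per group and language")
        if self.task not in ("spiral", "sentence"):
            raise ValueError(f"unknown task {self.task!r}")


# ------------------------------------------------------------- primitives


def _ar1(rng: np.random.Generator, n: int, mean: float, sd: float,
         rho: float = 0.995) -> np.ndarray:
    """Slowly varying autoregressive channel (pen orientation angles)."""
    noise = rng.standard_normal(n) * sd * np.sqrt(1 - rho**2)
    out = np.empty(n)
    out[0] = mean + rng.standard_normal() * sd
    for i in range(1, n):
        out[i] = mean + rho * (out[i - 1] - mean) + noise[i]
    return out


def _insert_lifts(
    rng: np.random.Generator, b: np.ndarray, t: np.ndarray, rate: float
) -> np.ndarray:
    """Poisson pen lifts of 0.1-0.3 s; never lifts the very first/last sample."""
    if rate <= 0:
        return b
    duration = t[-1] - t[0]
    n_events = rng.poisson(rate * duration)
    fs = 1.0 / np.median(np.diff(t))
    for _ in range(n_events):
        start = rng.uniform(t[0], t[-1])
        gap = rng.uniform(0.1, 0.3)
        i0 = max(1, int(np.searchsorted(t, start)))
        i1 = min(len(b) - 1, i0 + max(2, int(round(gap * fs))))
        b[i0:i1] = 0.0
    return b


def _finalize(
    rng: np.random.Generator,
    x: np.ndarray,
    y: np.ndarray,
    t: np.ndarray,
    b: np.ndarray,
    profile: EffectProfile,
    fs: float,
    meta: SubjectMeta,
) -> HandwritingRecord:
    """Add jitter, pressure, orientation channels; assemble the record."""
    n = len(t)
    x = x + rng.standard_normal(n) * profile.jitter_sd
    y = y + rng.standard_normal(n) * profile.jitter_sd
    b = _insert_lifts(rng, b.copy(), t, profile.extra_lift_rate)
    pressure = np.where(
        b == 1.0,
        np.clip(512.0 * profile.pressure_scale
                + rng.standard_normal(n) * 15.0, 1.0, 1023.0),
        0.0,
    )
    tilt = np.clip(_ar1(rng, n, 60.0, 4.0), 0.0, 90.0)
    azimuth = np.clip(_ar1(rng, n, 200.0, 8.0), 0.0, 359.0)
    return HandwritingRecord(
        x=x, y=y, t=t, b=b, p=pressure, tilt=tilt, azimuth=azimuth,
        fs=fs, meta=meta,
    )


# ------------------------------------------------------------------ spiral


def simulate_spiral(
    profile: EffectProfile,
    seed: int | np.random.SeedSequence = 0,
    fs: float = 133.0,
    meta: SubjectMeta | None = None,
) -> HandwritingRecord:
    """One Archimedean-spiral drawing r = c1*theta traversed at
    near-constant speed.

    Per subject, the radial growth c1 ~ N(2, 0.2^2) mm/rad over 3-5
    revolutions and the base speed v0 ~ N(30, 5^2) mm/s; the profile
    then scales speed, shrinks the radius per revolution (micrographia),
    and adds radial tremor, jitter, pressure reduction and pen lifts.
    """
    profile = profile.resolve()
    rng = np.random.default_rng(seed)
    c1 = max(0.5, rng.normal(2.0, 0.2))
    revolutions = rng.uniform(3.0, 5.0)
    v0 = max(5.0, rng.normal(30.0, 5.0)) * profile.velocity_scale

    theta_max = 2 * np.pi * revolutions
    fine = np.linspace(1e-3, theta_max, 20000)
    # arc length of r = c1*theta: ds = c1*sqrt(1+theta^2) dtheta
    ds = c1 * np.sqrt(1 + fine**2)
    s_of_theta = np.concatenate(
        ([0.0], np.cumsum((ds[1:] + ds[:-1]) / 2 * np.diff(fine)))
    )
    total_len = s_of_theta[-1]

    # speed with a slow 10% modulation; integrate to distance vs time
    t_end = total_len / v0 * 1.05  # margin for the modulation dips
    n = int(np.floor(t_end * fs)) + 1
    t = np.arange(n) / fs
    v = v0 * (1 + 0.1 * np.sin(2 * np.pi * 0.4 * t + rng.uniform(0, 2 * np.pi)))
    dist = np.concatenate(([0.0], np.cumsum((v[1:] + v[:-1]) / 2 / fs)))
    keep = dist <= total_len
    t, dist = t[keep], dist[keep]
    if len(t) < 50:  # degenerate profile; keep a minimal trace
        t = np.arange(50) / fs
        dist = np.linspace(0, total_len, 50)

    theta = np.interp(dist, s_of_theta, fine)
    rev_idx = theta / (2 * np.pi)
    radius = c1 * theta * (1 - profile.amplitude_decay) ** rev_idx
    phase = rng.uniform(0, 2 * np.pi)
    radius = radius + profile.tremor_amp * np.sin(
        2 * np.pi * profile.tremor_freq * t + phase
    )
    x = radius * np.cos(theta)
    y = radius * np.sin(theta)
    b = np.ones(len(t))
    meta = meta or SubjectMeta(task="spiral")
    return _finalize(rng, x, y, t, b, profile, fs, meta)


# ---------------------------------------------------------------- sentence


def simulate_sentence(
    profile: EffectProfile,
    style: LanguageStyle = LanguageStyle(),
    seed: int | np.random.SeedSequence = 0,
    fs: float = 133.0,
    meta: SubjectMeta | None = None,
) -> HandwritingRecord:
    """A stochastic oscillatory 'sentence': a left-to-right sequence of
    loopy strokes with in-air transitions.

    Letterforms are not meant to be legible; what matters is that the
    trace has sentence-like stroke structure, language-dependent style
    (stroke count, letter height, slant) and the same PD deficits as
    the spiral task.  Per-stroke amplitude shrinks by
    ``(1 - amplitude_decay) ** stroke_index`` (micrographia).
    """
    profile = profile.resolve()
    rng = np.random.default_rng(seed)
    n_strokes = int(rng.integers(style.stroke_count_range[0],
                                 style.stroke_count_range[1] + 1))
    h = style.letter_height_mm
    slant = np.tan(np.deg2rad(style.slant_deg))
    v_base = max(5.0, rng.normal(30.0, 5.0)) * profile.velocity_scale
    # stroke length scales with letter size; duration follows from speed
    phase = rng.uniform(0, 2 * np.pi)

    xs, ys, bs = [], [], []
    cursor = 0.0
    t_cur = 0.0
    ts = []
    for k in range(n_strokes):
        amp = h * (1 - profile.amplitude_decay) ** k
        stroke_len = amp * rng.uniform(1.5, 3.0)
        dur = max(0.12, stroke_len / v_base)
        m = max(4, int(round(dur * fs)))
        tt = t_cur + np.arange(m) / fs
        u = np.linspace(0, 1, m)
        freq = rng.uniform(1.0, 2.5)  # loops per stroke
        width = amp * rng.uniform(0.5, 1.2)
        sx = cursor + width * u + 0.25 * amp * np.sin(
            2 * np.pi * freq * u + rng.uniform(0, 2 * np.pi)
        )
        sy = 0.5 * amp * np.sin(2 * np.pi * freq * u + phase) + slant * (
            sx - cursor
        )
        # tremor rides on the vertical channel during the stroke
        sy = sy + profile.tremor_amp * np.sin(
            2 * np.pi * profile.tremor_freq * tt + phase
        )
        xs.append(sx)
        ys.append(sy)
        ts.append(tt)
        bs.append(np.ones(m))
        cursor += width + amp * rng.uniform(0.15, 0.45)
        t_cur = tt[-1] + 1.0 / fs

        if k < n_strokes - 1:  # in-air transition to the next stroke
            gap = rng.uniform(0.08, 0.25)
            g = max(2, int(round(gap * fs)))
            gt = t_cur + np.arange(g) / fs
            gx = np.linspace(sx[-1], cursor, g)
            gy = np.linspace(sy[-1], 0.0, g)
            xs.append(gx)
            ys.append(gy)
            ts.append(gt)
            bs.append(np.zeros(g))
            t_cur = gt[-1] + 1.0 / fs

    x = np.concatenate(xs)
    y = np.concatenate(ys)
    t = np.concatenate(ts)
    b = np.concatenate(bs)
    meta = meta or SubjectMeta(task="sentence")
    return _finalize(rng, x, y, t, b, profile, fs, meta)


# ------------------------------------------------------------------ cohort


def simulate_cohort(
    config: CohortConfig,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, list[HandwritingRecord]]:
    """Generate a full PD/HC cohort; optionally write SVC files + manifest.

    PD subjects draw their deficits from ``config.effects`` (or its
    neutral resolution in null mode); HC subjects always use the
    neutral profile with the same jitter.  Language style applies to
    both groups.  Returns (manifest, records); when ``out_dir`` is
    given, SVC files and ``manifest.csv`` are written there and the
    manifest's ``path`` column points at the files.
    """
    root = np.random.SeedSequence(config.seed)
    rows = []
    records: list[HandwritingRecord] = []
    hc_profile = replace(NEUTRAL_PROFILE, jitter_sd=config.effects.jitter_sd)
    subject_index = 0
    for language in config.languages:
        style = config.language_styles.get(language, LanguageStyle())
        for label in ("PD", "HC"):
            profile = config.effects if label == "PD" else hc_profile
            for _ in range(config.n_per_group_per_language):
                sid = f"{language}-{label}-{subject_index:04d}"
                meta = SubjectMeta(
                    subject_id=sid, label=label, language=language,
                    task=config.task,
                )
                child = np.random.SeedSequence(
                    entropy=config.seed, spawn_key=(subject_index,)
                )
                if config.task == "spiral":
                    rec = simulate_spiral(profile, child, config.fs, meta)
                else:
                    rec = simulate_sentence(profile, style, child, config.fs,
                                            meta)
                records.append(rec)
                rows.append({
                    "subject_id": sid, "label": label, "language": language,
                    "task": config.task, "path": f"{sid}.svc",
                })
                subject_index += 1

    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec, row in zip(records, rows):
            target = out / row["path"]
            if target.exists():
                raise FileExistsError(f"output collision: {target}")
            write_svc(rec, target)
        manifest = manifest.assign(
            path=[str(out / r["path"]) for r in rows]
        )
        write_manifest(manifest, out / "manifest.csv")
    return manifest, records
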