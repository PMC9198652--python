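"""Full I/O pipeline on one SVC file: read, normalise, resample, segment.

Writes a raw recording in device units (position counts, millisecond
ticks) to disk, then runs the standard preprocessing chain and prints
what each stage did.
"""

from pathlib import Path

import numpy as np

from graphomotor import (
    DeviceProfile,
    normalize_units,
    read_svc,
    segment_strokes,
    simulate_sentence,
    to_uniform_rate,
    write_svc,
    NEUTRAL_PROFILE,
)

out = Path("scratch")
out.mkdir(exist_ok=True)
path = out / "raw_sentence.svc"

# fabricate a raw device export: positions in counts (100/mm), time in ms
rec = simulate_sentence(NEUTRAL_PROFILE, seed=5, fs=180.0)
raw = rec.copy_with(x=rec.x * 100, y=rec.y * 100, t=rec.t * 1000)
write_svc(raw, path)

loaded = read_svc(path, fs=raw.fs)
print(f"loaded {len(loaded)} samples; x range "
      f"{loaded.x.min():.0f}..{loaded.x.max():.0f} counts")

norm = normalize_units(loaded, DeviceProfile(counts_per_mm=100,
                                             ticks_per_second=1000))
print(f"after unit normalisation: width {np.ptp(norm.x):.1f} mm, "
      f"duration {norm.duration:.2f} s")

uniform = to_uniform_rate(norm, target_fs=133.0)
print(f"resampled 180 -> 133 Hz: {len(uniform)} samples")

strokes = segment_strokes(uniform)
on = sum(1 for s in strokes if s.kind == "on_surface")
print(f"{len(strokes)} strokes ({on} on-surface, {len(strokes) - on} in-air)")
# The stroke count reflects the sentence's letter-like units: each
# on-surface stroke is one continuous pen-down movement.
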