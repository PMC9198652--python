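"""Rendering pen trajectories to offline handwriting images.

Only the on-surface trajectory is drawn — the rendered image is the
visual product of writing, exactly what an examiner would see on paper.
Strokes become connected 1-px polylines (dark trace on white), the
bounding box is padded by 5 %, letterboxed to a square to preserve
aspect, drawn on a working canvas, and resized to 224x224 with
nearest-neighbour interpolation (the input size of standard ImageNet
backbones).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .records import HandwritingRecord, segment_strokes, strokes_of

__all__ = ["RenderedImage", "render_offline_image"]

OUTPUT_SIZE = 224
_CANVAS = 448  # pre-resize working canvas


@dataclass
class RenderedImage:
    """224x224x3 float image in [0, 1]; white background, dark trace."""

    pixels: np.ndarray
    subject_id: str = ""
    task: str = ""

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    def dark_fraction(self, threshold: float = 0.5) -> float:
        return float(np.mean(self.pixels[..., 0] < threshold))

    def to_png(self, path: str | Path) -> None:
        img = Image.fromarray((self.pixels * 255).astype(np.uint8))
        img.save(path)


def render_offline_image(
    record: HandwritingRecord,
    size: int = OUTPUT_SIZE,
    line_width: int = 1,
) -> RenderedImage:
    """Rasterise the on-surface trace of a record.

    Raises ValueError when the record has no on-surface samples (the
    image would be blank).
    """
    strokes = strokes_of(segment_strokes(record), "on_surface")
    if not strokes:
        raise ValueError("no on-surface samples; refusing to render a blank image")

    idx = np.concatenate(
        [np.arange(s.start_index, s.end_index + 1) for s in strokes]
    )
    x, y = record.x[idx], record.y[idx]
    x0, x1 = float(x.min()), float(x.max())
    y0, y1 = float(y.min()), float(y.max())
    span = max(x1 - x0, y1 - y0)
    span = span if span > 0 else 1.0
    pad = 0.05 * span
    side = span + 2 * pad
    # letterbox: centre the bounding box in a square of side `side`
    ox = x0 - pad - (side - (x1 - x0 + 2 * pad)) / 2
    oy = y0 - pad - (side - (y1 - y0 + 2 * pad)) / 2
    scale = (_CANVAS - 1) / side

    img = Image.new("L", (_CANVAS, _CANVAS), color=255)
    draw = ImageDraw.Draw(img)
    for s in strokes:
        px = (record.x[s.sl] - ox) * scale
        # y axis flips: mm space grows upward, screen rows grow downward
        py = (_CANVAS - 1) - (record.y[s.sl] - oy) * scale
        pts = list(zip(px.tolist(), py.tolist()))
        if len(pts) == 1:
            draw.point(pts, fill=0)
        else:
            draw.line(pts, fill=0, width=line_width)

    img = img.resize((size, size), resample=Image.NEAREST)
    gray = np.asarray(img, dtype=float) / 255.0
    pixels = np.repeat(gray[:, :, None], 3, axis=2)
    return RenderedImage(
        pixels=pixels, subject_id=record.meta.subject_id, task=record.meta.task
    )
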