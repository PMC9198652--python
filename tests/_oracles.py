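"""Independent brute-force oracles used only by the test suite."""

from fractions import Fraction

import numpy as np


def orient(o, a, b) -> Fraction:
    """Exact orientation predicate via rational arithmetic."""
    ox, oy = Fraction(o[0]), Fraction(o[1])
    ax, ay = Fraction(a[0]), Fraction(a[1])
    bx, by = Fraction(b[0]), Fraction(b[1])
    return (ax - ox) * (by - oy) - (ay - oy) * (bx - ox)


def brute_force_crossings(a, b=None, self_mode=False) -> int:
    """O(n*m) all-pairs transversal crossing count with exact arithmetic."""
    a = [tuple(p) for p in np.asarray(a, dtype=float)]
    segs_a = [
        (a[i], a[i + 1], i) for i in range(len(a) - 1) if a[i] != a[i + 1]
    ]
    if self_mode:
        segs_b = segs_a
    else:
        b = [tuple(p) for p in np.asarray(b, dtype=float)]
        segs_b = [
            (b[i], b[i + 1], i) for i in range(len(b) - 1) if b[i] != b[i + 1]
        ]
    count = 0
    for p1, p2, i in segs_a:
        for p3, p4, j in segs_b:
            if self_mode and j <= i + 1:
                continue
            d1 = orient(p3, p4, p1)
            d2 = orient(p3, p4, p2)
            d3 = orient(p1, p2, p3)
            d4 = orient(p1, p2, p4)
            if d1 * d2 < 0 and d3 * d4 < 0:
                count += 1
            elif d1 == d2 == d3 == d4 == 0:
                lox = max(min(p1[0], p2[0]), min(p3[0], p4[0]))
                hix = min(max(p1[0], p2[0]), max(p3[0], p4[0]))
                loy = max(min(p1[1], p2[1]), min(p3[1], p4[1]))
                hiy = min(max(p1[1], p2[1]), max(p3[1], p4[1]))
                if lox <= hix and loy <= hiy and (lox < hix or loy < hiy):
                    count += 1
    return count


def pairwise_slope_median(y, t) -> float:
    """Theil-Sen oracle: explicit median over all pairwise slopes."""
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    slopes = [
        (y[j] - y[i]) / (t[j] - t[i])
        for i in range(len(y))
        for j in range(i + 1, len(y))
        if t[j] != t[i]
    ]
    return float(np.median(slopes))


def bresenham_trace_pixels(record, canvas=448, out=224) -> int:
    """Independent rasterisation oracle: integer Bresenham lines on the
    same letterboxed canvas, nearest-neighbour subsampled; returns the
    dark-pixel count of the 224x224 image."""
    from graphomotor.records import segment_strokes, strokes_of

    strokes = strokes_of(segment_strokes(record), "on_surface")
    idx = np.concatenate(
        [np.arange(s.start_index, s.end_index + 1) for s in strokes]
    )
    x, y = record.x[idx], record.y[idx]
    x0, x1 = x.min(), x.max()
    y0, y1 = y.min(), y.max()
    span = max(x1 - x0, y1 - y0) or 1.0
    pad = 0.05 * span
    side = span + 2 * pad
    ox = x0 - pad - (side - (x1 - x0 + 2 * pad)) / 2
    oy = y0 - pad - (side - (y1 - y0 + 2 * pad)) / 2
    scale = (canvas - 1) / side

    grid = np.zeros((canvas, canvas), dtype=bool)

    def draw_line(c0, r0, c1, r1):
        dc, dr = abs(c1 - c0), -abs(r1 - r0)
        sc = 1 if c0 < c1 else -1
        sr = 1 if r0 < r1 else -1
        err = dc + dr
        while True:
            grid[r0, c0] = True
            if c0 == c1 and r0 == r1:
                break
            e2 = 2 * err
            if e2 >= dr:
                err += dr
                c0 += sc
            if e2 <= dc:
                err += dc
                r0 += sr

    for s in strokes:
        px = np.rint((record.x[s.sl] - ox) * scale).astype(int)
        py = np.rint((canvas - 1) - (record.y[s.sl] - oy) * scale).astype(int)
        for k in range(len(px) - 1):
            draw_line(px[k], py[k], px[k + 1], py[k + 1])
        if len(px) == 1:
            grid[py[0], px[0]] = True

    # nearest-neighbour subsample to the output size (PIL convention:
    # sample at the centre of each output pixel)
    centers = ((np.arange(out) + 0.5) * canvas / out).astype(int)
    small = grid[np.ix_(centers, centers)]
    return int(small.sum())
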