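"""Polyline geometry: path length and segment-crossing counts.

Intersection counts quantify how often the pen trace crosses itself
(within one stroke) or another stroke.  A "crossing" is a transversal
intersection of two segments: the segments genuinely pass through each
other.  Touching at a shared stroke endpoint does not count, and in
self mode adjacent segments (which share a vertex by construction) are
excluded.  Collinear overlapping segment pairs count once per pair.

Candidate pairs are prefiltered by bounding-box overlap (in blocks, to
bound memory) and only survivors get the exact orientation test; pen
segments are short relative to the trace, so the filter removes almost
all pairs.  Tests check the result against an exact-arithmetic
brute-force oracle.
"""

from __future__ import annotations

import numpy as np

__all__ = ["polyline_length", "count_polyline_intersections"]


def polyline_length(points: np.ndarray) -> float:
    """Sum of Euclidean segment lengths of an (n, 2) point sequence."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return 0.0
    return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))


def _segments(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pts = np.asarray(points, dtype=float)
    a, b = pts[:-1], pts[1:]
    # drop zero-length (degenerate) segments but remember original indices
    keep = np.any(a != b, axis=1)
    return np.column_stack([a[keep], b[keep]]), np.flatnonzero(keep)


def _cross(ox, oy, ax, ay, bx, by):
    """Orientation cross product (a - o) x (b - o), vectorised."""
    return (ax - ox) * (by - oy) - (ay - oy) * (bx - ox)


def count_polyline_intersections(
    a: np.ndarray, b: np.ndarray | None = None, self_mode: bool = False
) -> int:
    """Count transversal crossings between two polylines.

    Parameters
    ----------
    a, b : (n, 2) vertex arrays.  In ``self_mode`` only ``a`` is used
        and segment pairs that are adjacent (share a vertex index) are
        skipped, so a figure-eight counts exactly one self-crossing.

    Crossing rule: strict transversal intersection (each segment's
    endpoints lie on opposite sides of the other's supporting line);
    endpoint touching is not a crossing; collinear overlap over more
    than a point counts once per pair.
    """
    seg_a, idx_a = _segments(a)
    if self_mode:
        seg_b, idx_b = seg_a, idx_a
    else:
        if b is None:
            raise ValueError("second polyline required unless self_mode")
        seg_b, idx_b = _segments(b)
    if len(seg_a) == 0 or len(seg_b) == 0:
        return 0

    box_a = _bboxes(seg_a)
    box_b = _bboxes(seg_b)

    total = 0
    block = 2048
    for i0 in range(0, len(seg_a), block):
        sa = seg_a[i0 : i0 + block]
        ba = box_a[i0 : i0 + block]
        ia = idx_a[i0 : i0 + block]
        for j0 in range(0, len(seg_b), block):
            sb = seg_b[j0 : j0 + block]
            bb = box_b[j0 : j0 + block]
            jb = idx_b[j0 : j0 + block]

            cand = (
                (ba[:, 0][:, None] <= bb[:, 2][None, :])
                & (ba[:, 2][:, None] >= bb[:, 0][None, :])
                & (ba[:, 1][:, None] <= bb[:, 3][None, :])
                & (ba[:, 3][:, None] >= bb[:, 1][None, :])
            )
            if self_mode:
                # count each unordered non-adjacent pair once
                cand &= jb[None, :] > ia[:, None] + 1
            ii, jj = np.nonzero(cand)
            if len(ii) == 0:
                continue
            total += _count_pairs(sa[ii], sb[jj])
    return total


def _bboxes(seg: np.ndarray) -> np.ndarray:
    """Per-segment (min_x, min_y, max_x, max_y)."""
    return np.column_stack([
        np.minimum(seg[:, 0], seg[:, 2]), np.minimum(seg[:, 1], seg[:, 3]),
        np.maximum(seg[:, 0], seg[:, 2]), np.maximum(seg[:, 1], seg[:, 3]),
    ])


def _count_pairs(sa: np.ndarray, sb: np.ndarray) -> int:
    """Exact crossing test on aligned candidate segment pairs."""
    p1x, p1y, p2x, p2y = sa[:, 0], sa[:, 1], sa[:, 2], sa[:, 3]
    p3x, p3y, p4x, p4y = sb[:, 0], sb[:, 1], sb[:, 2], sb[:, 3]

    d1 = _cross(p3x, p3y, p4x, p4y, p1x, p1y)
    d2 = _cross(p3x, p3y, p4x, p4y, p2x, p2y)
    d3 = _cross(p1x, p1y, p2x, p2y, p3x, p3y)
    d4 = _cross(p1x, p1y, p2x, p2y, p4x, p4y)

    proper = (d1 * d2 < 0) & (d3 * d4 < 0)

    # collinear overlap: all orientations zero and bounding boxes overlap
    # in more than a single point
    col = (d1 == 0) & (d2 == 0) & (d3 == 0) & (d4 == 0)
    if np.any(col):
        lox = np.maximum(np.minimum(p1x, p2x), np.minimum(p3x, p4x))
        hix = np.minimum(np.maximum(p1x, p2x), np.maximum(p3x, p4x))
        loy = np.maximum(np.minimum(p1y, p2y), np.minimum(p3y, p4y))
        hiy = np.minimum(np.maximum(p1y, p2y), np.maximum(p3y, p4y))
        overlap = ((lox <= hix) & (loy <= hiy)) & ((lox < hix) | (loy < hiy))
        col &= overlap
    return int(np.count_nonzero(proper | col))
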