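"""Compiled inner loops for trace rasterization.

The swimming trace of one feedback cycle is the union of ink disks
stamped along each agent's sub-tick polyline (see trace_imaging for the
exact definition).  A pixel is inked iff its centre lies within the ink
radius of at least one stamp point; the kernel additionally accumulates
the per-square pixel counts (trace momentum) incrementally via a
pixel -> square label map.
"""

from __future__ import annotations

import math

import numba as nb


@nb.njit(cache=True, inline="always")
def _stamp_disk(cx, cy, r, res, raster, labels, tm):
    """Ink all pixels whose centre is within r (um) of (cx, cy)."""
    if r <= 0.0:
        return
    r2 = r * r
    h, w = raster.shape
    iy0 = int(math.ceil((cy - r) / res - 0.5))
    iy1 = int(math.floor((cy + r) / res - 0.5))
    if iy0 < 0:
        iy0 = 0
    if iy1 > h - 1:
        iy1 = h - 1
    ix0 = int(math.ceil((cx - r) / res - 0.5))
    ix1 = int(math.floor((cx + r) / res - 0.5))
    if ix0 < 0:
        ix0 = 0
    if ix1 > w - 1:
        ix1 = w - 1
    for iy in range(iy0, iy1 + 1):
        dy = (iy + 0.5) * res - cy
        dy2 = dy * dy
        if dy2 > r2:
            continue
        for ix in range(ix0, ix1 + 1):
            dx = (ix + 0.5) * res - cx
            if dx * dx + dy2 <= r2:
                if not raster[iy, ix]:
                    raster[iy, ix] = True
                    tm[labels[iy, ix]] += 1


@nb.njit(cache=True)
def stamp_polylines(pts, ink_radii, res, delta, raster, labels, tm):
    """Rasterise agent polylines into ``raster`` and accumulate ``tm``.

    pts        : (A, S+1, 2) float64, sub-tick positions in um
    ink_radii  : (A, S) float64, per-segment ink radius in um
                 (<= 0 disables inking for that segment)
    res        : pixel edge length, um
    delta      : stamp spacing along segments, um
    raster     : (H, W) bool, modified in place
    labels     : (H, W) int16 pixel -> square map (0 = no square)
    tm         : (26,) int64, tm[k] incremented per newly inked pixel of
                 square k (tm[0] collects wall/passage pixels)
    """
    A = pts.shape[0]
    S = pts.shape[1] - 1
    for a in range(A):
        _stamp_disk(pts[a, 0, 0], pts[a, 0, 1], ink_radii[a, 0], res, raster, labels, tm)
        for s in range(S):
            x0 = pts[a, s, 0]
            y0 = pts[a, s, 1]
            dx = pts[a, s + 1, 0] - x0
            dy = pts[a, s + 1, 1] - y0
            seg = math.sqrt(dx * dx + dy * dy)
            if seg <= 0.0:
                continue
            r = ink_radii[a, s]
            n = int(math.ceil(seg / delta))
            for k in range(1, n + 1):
                t = k / n
                _stamp_disk(x0 + t * dx, y0 + t * dy, r, res, raster, labels, tm)
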