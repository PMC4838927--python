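"""Independent brute-force oracles used by the test suite.

Each oracle reimplements an operation from first principles (per-pixel
enumeration, flood fill, explicit sorting) without touching the
production code paths it checks.
"""

from __future__ import annotations

import math

import numpy as np


def stroke_samples(polyline, radii, delta):
    """Stamp points + radii of a stroked polyline.

    The trace is defined as the union of ink disks at the polyline's
    first vertex and at points spaced ``seg_len / ceil(seg_len / delta)``
    along every segment (endpoints included); zero-length segments
    contribute nothing beyond the first vertex.
    """
    pts = [np.asarray(polyline[0], dtype=float)]
    rads = [float(radii[0])]
    for s in range(len(polyline) - 1):
        p0 = np.asarray(polyline[s], dtype=float)
        p1 = np.asarray(polyline[s + 1], dtype=float)
        seg = float(np.hypot(*(p1 - p0)))
        if seg <= 0:
            continue
        n = int(math.ceil(seg / delta))
        for k in range(1, n + 1):
            pts.append(p0 + (k / n) * (p1 - p0))
            rads.append(float(radii[s]))
    return np.array(pts), np.array(rads)


def raster_oracle(polylines, seg_radii, shape, resolution, delta):
    """Per-pixel brute-force rasterisation of stroked polylines.

    A pixel is inked iff its centre lies within the ink radius of at
    least one stamp point of any agent.  Quadratic in pixels x stamps;
    only usable on small windows.
    """
    h, w = shape
    ys = (np.arange(h) + 0.5) * resolution
    xs = (np.arange(w) + 0.5) * resolution
    out = np.zeros((h, w), dtype=bool)
    for poly, radii in zip(polylines, seg_radii):
        pts, rads = stroke_samples(poly, radii, delta)
        keep = rads > 0
        pts, rads = pts[keep], rads[keep]
        if pts.size == 0:
            continue
        for iy, py in enumerate(ys):
            d2y = (py - pts[:, 1]) ** 2
            for ix, px in enumerate(xs):
                if out[iy, ix]:
                    continue
                d2 = (px - pts[:, 0]) ** 2 + d2y
                if np.any(d2 <= rads ** 2):
                    out[iy, ix] = True
    return out


def flood_fill_clusters(grid):
    """Count 4-connected True components by explicit flood fill."""
    grid = np.asarray(grid, dtype=bool)
    seen = np.zeros_like(grid)
    rows, cols = grid.shape
    count = 0
    for r0 in range(rows):
        for c0 in range(cols):
            if grid[r0, c0] and not seen[r0, c0]:
                count += 1
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < rows and 0 <= cc < cols
                                and grid[rr, cc] and not seen[rr, cc]):
                            seen[rr, cc] = True
                            stack.append((rr, cc))
    return count


def boundary_enumeration(grid):
    """Count differing 4-adjacent pairs by explicit enumeration."""
    grid = np.asarray(grid, dtype=bool)
    rows, cols = grid.shape
    n = 0
    for r in range(rows):
        for c in range(cols):
            if c + 1 < cols and grid[r, c] != grid[r, c + 1]:
                n += 1
            if r + 1 < rows and grid[r, c] != grid[r + 1, c]:
                n += 1
    return n


def ranking_oracle(values, select, k):
    """k lowest/highest entries via explicit stable sorting on
    (value, index) pairs; returns a boolean lit mask."""
    pairs = sorted((v if select == "lowest" else -v, i)
                   for i, v in enumerate(values))
    mask = np.zeros(len(values), dtype=bool)
    for _, i in pairs[:k]:
        mask[i] = True
    return mask
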