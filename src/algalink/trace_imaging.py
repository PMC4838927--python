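"""Trace images and the trace-momentum (TM) statistic.

One feedback cycle's swimming traces are rendered into a binary raster
covering the chamber bounding box, and the TM vector is the per-square
count of inked pixels.  TM is the activity proxy driving both feedback
algorithms: more cells swimming at faster speeds cover more pixels.

Trace definition
----------------
Each agent contributes a polyline of sub-tick positions.  Every segment
is stroked by stamping *ink disks* of radius ``width/2 + resolution/2``
at points spaced ``<= resolution`` um along the segment (endpoints
included; the polyline's first vertex is always stamped so a stationary
agent still marks its body footprint).  A pixel is inked iff its centre
lies within the ink radius of at least one stamp point.  The half-pixel
dilation guarantees that strokes thinner than a pixel still mark the
raster.  The union over agents is binary; overlapping traces are counted
once, which makes TM saturate at high cell density.

Pixels whose centres fall on walls or inside passages belong to no
square and never contribute to TM.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
import math

import numpy as np

from . import _kernels
from .errors import ConfigurationError, UndefinedRatioError
from .geometry import GROUP_I, GROUP_II, GridLayout, square_index_of

#: default raster resolution, um per pixel (square = 120 x 120 px)
DEFAULT_RESOLUTION = 4.0


@dataclass
class TraceImage:
    """Binary occupancy raster of one feedback cycle's traces."""

    resolution: float
    pixels: np.ndarray  # bool (H, W); pixel centre = ((ix+0.5)*res, (iy+0.5)*res)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def to_png(self, path) -> None:
        """Write the binary raster as a PNG image."""
        import matplotlib.image

        matplotlib.image.imsave(path, self.pixels, cmap="gray_r", vmin=0, vmax=1)


@dataclass
class TMVector:
    """25 per-square inked-pixel counts for one time step."""

    tm: np.ndarray  # int64 (25,), ordered by square index 1..25
    step: int = -1

    def __post_init__(self):
        self.tm = np.asarray(self.tm, dtype=np.int64)
        if self.tm.shape != (25,):
            raise ConfigurationError("TM vector must have 25 entries")
        if (self.tm < 0).any():
            raise ConfigurationError("TM counts must be non-negative")

    def __getitem__(self, square_index: int) -> int:
        """1-based access by square index."""
        return int(self.tm[square_index - 1])


def raster_shape(layout: GridLayout, resolution: float = DEFAULT_RESOLUTION) -> tuple[int, int]:
    n = int(math.ceil(layout.side / resolution))
    return (n, n)


@lru_cache(maxsize=8)
def pixel_labels(layout: GridLayout, resolution: float = DEFAULT_RESOLUTION) -> np.ndarray:
    """Pixel-centre -> square-index map (int16; 0 for walls/passages)."""
    h, w = raster_shape(layout, resolution)
    xs = (np.arange(w) + 0.5) * resolution
    ys = (np.arange(h) + 0.5) * resolution
    gx, gy = np.meshgrid(xs, ys)
    return square_index_of(gx, gy, layout).astype(np.int16)


def ink_radius(width: float, resolution: float) -> float:
    """Ink radius (um) of a stroke of the given body width."""
    return width / 2.0 + resolution / 2.0


def _as_polyline_batch(trajectories, widths):
    """Normalise inputs to (A, S+1, 2) points + (A, S) widths."""
    if isinstance(trajectories, np.ndarray) and trajectories.ndim == 3:
        pts = np.asarray(trajectories, dtype=np.float64)
    else:
        polys = [np.atleast_2d(np.asarray(p, dtype=np.float64)) for p in trajectories]
        if not polys:
            return np.empty((0, 1, 2)), np.empty((0, 1))
        smax = max(p.shape[0] for p in polys)
        pts = np.empty((len(polys), smax, 2), dtype=np.float64)
        for i, p in enumerate(polys):
            pts[i, : p.shape[0]] = p
            pts[i, p.shape[0]:] = p[-1]  # pad by repeating the last vertex
    nseg = max(pts.shape[1] - 1, 1)
    w = np.asarray(widths, dtype=np.float64)
    if w.ndim == 0:
        w = np.full((pts.shape[0], nseg), float(w))
    elif w.ndim == 1:
        w = np.repeat(w[:, None], nseg, axis=1)
    if w.shape != (pts.shape[0], nseg):
        raise ConfigurationError("widths shape does not match trajectories")
    return pts, w


def render_cycle(
    trajectories,
    widths,
    layout: GridLayout,
    resolution: float = DEFAULT_RESOLUTION,
) -> TraceImage:
    """Render one cycle's agent trajectories into a binary trace image.

    Parameters
    ----------
    trajectories
        Either an (A, S+1, 2) array of per-agent sub-tick positions (um)
        or a sequence of per-agent (S_i+1, 2) polylines.
    widths
        Stroke width(s) in um: scalar, per-agent (A,), or per-segment
        (A, S).  Non-positive widths disable inking of that segment.
    """
    pts, w = _as_polyline_batch(trajectories, widths)
    h, wpx = raster_shape(layout, resolution)
    raster = np.zeros((h, wpx), dtype=np.bool_)
    if pts.shape[0]:
        labels = pixel_labels(layout, resolution)
        tm = np.zeros(26, dtype=np.int64)
        radii = np.where(w > 0, w / 2.0 + resolution / 2.0, -1.0)
        if pts.shape[1] == 1:  # single points: treat as zero-length polylines
            pts = np.concatenate([pts, pts], axis=1)
        _kernels.stamp_polylines(pts, radii, resolution, resolution, raster, labels, tm)
    return TraceImage(resolution=resolution, pixels=raster)


def compute_tm(image: TraceImage, layout: GridLayout, step: int = -1) -> TMVector:
    """Count inked pixels per square (passage/wall pixels excluded)."""
    labels = pixel_labels(layout, image.resolution)
    if labels.shape != image.pixels.shape:
        raise ConfigurationError(
            f"image shape {image.pixels.shape} does not match layout raster "
            f"{labels.shape} at resolution {image.resolution}"
        )
    counts = np.bincount(labels[image.pixels].ravel(), minlength=26)
    return TMVector(tm=counts[1:26], step=step)


def tm_ratio(tm: TMVector | np.ndarray, layout: GridLayout) -> float:
    """Signed group imbalance (TM_I - TM_II) / (TM_I + TM_II).

    The centre square is excluded.  Raises
    :class:`~algalink.errors.UndefinedRatioError` when both group sums
    are zero (callers treat this as "no flip").
    """
    values = tm.tm if isinstance(tm, TMVector) else np.asarray(tm)
    tm_i = float(values[layout.group_mask(GROUP_I)].sum())
    tm_ii = float(values[layout.group_mask(GROUP_II)].sum())
    total = tm_i + tm_ii
    if total == 0:
        raise UndefinedRatioError("both group TM sums are zero; ratio undefined")
    return (tm_i - tm_ii) / total
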