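"""Geometry of the 25-square micro-aquarium chip.

The chamber is a 5x5 array of square wells, each 480 um wide and 120 um
deep, connected to their 4-neighbours by short square passages
(90 x 90 um) centred on the shared wall.  Squares are indexed 1..25 in
row-major order from the upper-left to the lower-right corner.  For the
two-state flipping (oscillation) feedback the squares are split into two
interleaved groups of 12 ("I" and "II"); the geometric centre square
(index 13) belongs to neither group and is never illuminated.

Coordinates: origin at the outer upper-left corner of square 1, x to the
right, y downward, units um.  The chip depth is carried as metadata only;
all dynamics are 2-D top-view projections.

Region ownership is half-open: a square or passage owns its low-x / low-y
edge but not its high edge, so every interior point belongs to exactly
one region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .errors import ConfigurationError, OutOfDomainError

GROUP_I = "I"
GROUP_II = "II"
CENTER = "center"

#: region-code bands used by the vectorised classifier
_SQ_LO, _SQ_HI = 1, 25           # square index
_HP_BASE = 26                    # horizontal passages, 26..45
_VP_BASE = 46                    # vertical passages, 46..65


@dataclass(frozen=True)
class GridLayout:
    """Immutable 5x5 micro-aquarium layout (lengths in um)."""

    rows: int = 5
    cols: int = 5
    square_width: float = 480.0
    passage_width: float = 90.0
    passage_length: float = 90.0
    depth: float = 120.0  # metadata; unused by the 2-D dynamics

    # ------------------------------------------------------------------
    # derived scalars
    @property
    def pitch(self) -> float:
        """Centre-to-centre spacing of adjacent squares."""
        return self.square_width + self.passage_length

    @property
    def side(self) -> float:
        """Outer footprint side length (5*480 + 4*90 = 2760 for defaults)."""
        return self.cols * self.square_width + (self.cols - 1) * self.passage_length

    @property
    def passage_lo(self) -> float:
        """Offset of the passage band from a square's low edge."""
        return (self.square_width - self.passage_width) / 2.0

    @property
    def passage_hi(self) -> float:
        return self.passage_lo + self.passage_width

    @property
    def n_squares(self) -> int:
        return self.rows * self.cols

    @property
    def center_index(self) -> int:
        return self.rows * self.cols // 2 + 1  # 13 for 5x5

    # ------------------------------------------------------------------
    # indexing
    def index_of(self, row: int, col: int) -> int:
        return row * self.cols + col + 1

    def row_col(self, index: int) -> tuple[int, int]:
        self._check_index(index)
        return (index - 1) // self.cols, (index - 1) % self.cols

    def _check_index(self, index: int) -> None:
        if not 1 <= index <= self.n_squares:
            raise ConfigurationError(f"square index {index} outside 1..{self.n_squares}")

    def square_origin(self, index: int) -> tuple[float, float]:
        """Upper-left corner (x, y) of a square in um."""
        row, col = self.row_col(index)
        return col * self.pitch, row * self.pitch

    def square_center(self, index: int) -> tuple[float, float]:
        x0, y0 = self.square_origin(index)
        return x0 + self.square_width / 2.0, y0 + self.square_width / 2.0

    # ------------------------------------------------------------------
    # groups (parity checkerboard; centre excluded)
    def group_of(self, index: int) -> str:
        self._check_index(index)
        if index == self.center_index:
            return CENTER
        row, col = self.row_col(index)
        return GROUP_I if (row + col) % 2 == 1 else GROUP_II

    def group_indices(self, group: str) -> tuple[int, ...]:
        return tuple(i for i in range(1, self.n_squares + 1) if self.group_of(i) == group)

    def group_mask(self, group: str) -> np.ndarray:
        """Boolean mask over squares 1..25 (position i-1 <-> square i)."""
        mask = np.zeros(self.n_squares, dtype=bool)
        for i in self.group_indices(group):
            mask[i - 1] = True
        return mask

    # ------------------------------------------------------------------
    def iter_passages(self) -> Iterator[tuple[str, int, int]]:
        """All passage ids: ('h', row, col) joins (row,col)-(row,col+1),
        ('v', row, col) joins (row,col)-(row+1,col)."""
        for r in range(self.rows):
            for c in range(self.cols - 1):
                yield ("h", r, c)
        for r in range(self.rows - 1):
            for c in range(self.cols):
                yield ("v", r, c)

    def to_config_text(self) -> str:
        lines = [
            f"rows = {self.rows}",
            f"cols = {self.cols}",
            f"square_width_um = {self.square_width:g}",
            f"passage_width_um = {self.passage_width:g}",
            f"passage_length_um = {self.passage_length:g}",
            f"depth_um = {self.depth:g}",
        ]
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class Location:
    """Result of :func:`locate`: a square, a passage, or a wall point."""

    kind: str  # "square" | "passage" | "wall"
    square: int | None = None
    passage: tuple[str, int, int] | None = None


def build_layout(
    square_width: float = 480.0,
    passage_width: float = 90.0,
    passage_length: float = 90.0,
    depth: float = 120.0,
    rows: int = 5,
    cols: int = 5,
) -> GridLayout:
    """Validate geometry parameters and return a :class:`GridLayout`."""
    if rows != 5 or cols != 5:
        raise ConfigurationError("only the 5x5 chamber layout is supported")
    for name, val in (
        ("square_width", square_width),
        ("passage_width", passage_width),
        ("passage_length", passage_length),
        ("depth", depth),
    ):
        if not np.isfinite(val) or val <= 0:
            raise ConfigurationError(f"{name} must be positive, got {val!r}")
    if passage_width > square_width:
        raise ConfigurationError("passage_width cannot exceed square_width")
    return GridLayout(rows, cols, square_width, passage_width, passage_length, depth)


# ----------------------------------------------------------------------
# vectorised classification (used by the agent dynamics and rasteriser)

def region_code(x, y, layout: GridLayout) -> np.ndarray:
    """Classify points into integer region codes.

    0 = wall or outside, 1..25 = square index, 26..45 = horizontal
    passages (row-major), 46..65 = vertical passages (row-major).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    P = layout.pitch
    W = layout.square_width
    a0, a1 = layout.passage_lo, layout.passage_hi
    col = np.floor_divide(x, P).astype(np.int64)
    row = np.floor_divide(y, P).astype(np.int64)
    u = x - col * P
    v = y - row * P
    code = np.zeros(np.broadcast(x, y).shape, dtype=np.int64)
    in_rows = (row >= 0) & (row < layout.rows)
    in_cols = (col >= 0) & (col < layout.cols)
    sq = in_rows & in_cols & (u < W) & (v < W)
    hp = in_rows & (col >= 0) & (col < layout.cols - 1) & (u >= W) & (v >= a0) & (v < a1)
    vp = in_cols & (row >= 0) & (row < layout.rows - 1) & (v >= W) & (u >= a0) & (u < a1)
    np.copyto(code, row * layout.cols + col + 1, where=sq)
    np.copyto(code, _HP_BASE + row * (layout.cols - 1) + col, where=hp)
    np.copyto(code, _VP_BASE + row * layout.cols + col, where=vp)
    return code


def in_interior(x, y, layout: GridLayout) -> np.ndarray:
    """True where the point lies inside a square or a passage."""
    return region_code(x, y, layout) > 0


def square_index_of(x, y, layout: GridLayout) -> np.ndarray:
    """Square index 1..25 for points inside squares, else 0."""
    code = region_code(x, y, layout)
    return np.where((code >= _SQ_LO) & (code <= _SQ_HI), code, 0)


def _decode_passage(code: int, layout: GridLayout) -> tuple[str, int, int]:
    if _HP_BASE <= code < _VP_BASE:
        k = code - _HP_BASE
        return ("h", k // (layout.cols - 1), k % (layout.cols - 1))
    k = code - _VP_BASE
    return ("v", k // layout.cols, k % layout.cols)


def locate(point, layout: GridLayout) -> Location:
    """Map a single 2-D point (um) to its region.

    Raises :class:`OutOfDomainError` for points outside the bounding box
    ``[0, side) x [0, side)``.
    """
    x, y = float(point[0]), float(point[1])
    if not (0.0 <= x < layout.side and 0.0 <= y < layout.side):
        raise OutOfDomainError(f"point ({x}, {y}) outside the chamber bounding box")
    code = int(region_code(x, y, layout))
    if code == 0:
        return Location("wall")
    if code <= _SQ_HI:
        return Location("square", square=code)
    return Location("passage", passage=_decode_passage(code, layout))


def neighbors(index: int, layout: GridLayout) -> frozenset[int]:
    """4-neighbourhood of a square through its wall passages."""
    layout._check_index(index)
    row, col = layout.row_col(index)
    out = []
    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        r, c = row + dr, col + dc
        if 0 <= r < layout.rows and 0 <= c < layout.cols:
            out.append(layout.index_of(r, c))
    return frozenset(out)


def export_group_map(layout: GridLayout):
    """Group assignment as a DataFrame (index, row, col, group)."""
    import pandas as pd

    rows = []
    for i in range(1, layout.n_squares + 1):
        r, c = layout.row_col(i)
        rows.append({"index": i, "row": r, "col": c, "group": layout.group_of(i)})
    return pd.DataFrame(rows)
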