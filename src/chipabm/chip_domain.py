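"""Discretized 2-D representation of the filmed microfluidic-chip region.

The filmed sub-region of the chip is modeled as a rectangular lattice of
square grid cells of side ``dx = dy`` (12 um for the reference geometry).
Horizontally the lattice splits into three sections: a left chamber (tumor
cells), a central microchannel section, and a right chamber (leukocyte
entry).  The microchannel section consists of horizontal channels one grid
row high separated by solid interspaces that act as obstacles; interspace
rows restricted to the channel-section columns carry the occupancy label
``-1``, every other square is free (``0``).

Two coarse partitions of the lattice feed the summary statistics used for
inference: ten vertical column bands ("bins") and a 3x3 partition into
"quadrants".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .errors import GeometryError

#: Occupancy labels
FREE = 0
OBSTACLE = -1

#: Euclidean distances (in grid units) to the 8 Moore neighbors.
MOORE_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
MOORE_DISTANCES = [math.sqrt(di * di + dj * dj) for di, dj in MOORE_OFFSETS]


@dataclass(frozen=True)
class ChipGeometry:
    """Physical dimensions of the filmed chip sub-region, in micrometers.

    Defaults reproduce the reference device: a 1707 x 1452 um field of view
    with a 676 um left chamber, a 500 um channel section and a 531 um right
    chamber, bridged by 31 channels (12 um high) separated by 30 interspaces
    (33 um high), discretized on a 12 um square lattice.
    """

    lx: float = 1707.0
    ly: float = 1452.0
    dx: float = 12.0
    dy: float = 12.0
    left_width: float = 676.0
    center_width: float = 500.0
    right_width: float = 531.0
    channel_height: float = 12.0
    interspace_height: float = 33.0
    n_channels: int = 31
    n_interspaces: int = 30

    def __post_init__(self) -> None:
        lengths = (
            self.lx, self.ly, self.dx, self.dy, self.left_width,
            self.center_width, self.right_width, self.channel_height,
            self.interspace_height,
        )
        if any(v <= 0 for v in lengths):
            raise GeometryError("all chip dimensions must be strictly positive")
        if self.dx != self.dy:
            raise GeometryError("grid squares must be square (dx == dy)")
        if self.n_channels < 1 or self.n_interspaces < 0:
            raise GeometryError("need at least one channel and >= 0 interspaces")
        if self.n_interspaces != self.n_channels - 1:
            raise GeometryError(
                "n_interspaces must equal n_channels - 1 "
                f"(got {self.n_interspaces} vs {self.n_channels} channels)"
            )
        if (self.channel_height / self.dy) % 1.0 != 0.0:
            raise GeometryError("channel_height must be an integer number of grid rows")


def bin_index(col: int, n_col: int, n_bins: int = 10) -> int:
    """Map a 1-based column index to its 1-based bin id.

    Columns are partitioned into ``n_bins`` contiguous near-equal runs,
    ordered left to right.  When ``n_col`` is not divisible by ``n_bins`` the
    remainder columns are assigned to the rightmost bins, so bin 1 (the
    heavily weighted leftmost band) always has the base width
    ``n_col // n_bins``.
    """
    if not 1 <= col <= n_col:
        raise IndexError(f"column {col} outside 1..{n_col}")
    edges = _bin_edges(n_col, n_bins)
    return int(np.searchsorted(edges, col, side="left")) + 1


def _bin_edges(n_col: int, n_bins: int) -> np.ndarray:
    """Rightmost (inclusive, 1-based) column of each bin."""
    base, rem = divmod(n_col, n_bins)
    widths = [base] * (n_bins - rem) + [base + 1] * rem
    return np.cumsum(widths)


def _third_edges(n: int) -> np.ndarray:
    """Rightmost (inclusive, 1-based) index of each third; remainder pushed right/down."""
    base, rem = divmod(n, 3)
    widths = [base] * (3 - rem) + [base + 1] * rem
    return np.cumsum(widths)


class ChipDomain:
    """Discretized chip lattice with occupancy labels and partition maps.

    Grid squares are addressed 1-based as ``p = (i, j)`` with row ``i`` = 1 at
    the top of the filmed region and column ``j`` = 1 at its left edge; the
    square center carries physical coordinates ``(x_p, y_p)`` in um with y
    increasing upward.

    Built via :func:`build_domain`; holds cached neighbor tables used by the
    movement and diffusion kernels.
    """

    def __init__(self, geometry: ChipGeometry):
        self.geometry = geometry
        g = geometry
        self.n_left = math.ceil(g.left_width / g.dx)
        self.n_center = math.ceil(g.center_width / g.dx)
        self.n_right = math.ceil(g.right_width / g.dx)
        self.n_col = self.n_left + self.n_center + self.n_right
        self._rows_per_channel = int(g.channel_height / g.dy)
        self._rows_per_interspace = math.ceil(g.interspace_height / g.dy)
        self.n_row = (
            self._rows_per_channel * g.n_channels
            + self._rows_per_interspace * g.n_interspaces
        )

        # Row types: channels and interspaces alternate top to bottom,
        # starting and ending with a channel.
        interspace_row = np.zeros(self.n_row, dtype=bool)
        period = self._rows_per_channel + self._rows_per_interspace
        for r in range(self.n_row):
            interspace_row[r] = (r % period) >= self._rows_per_channel
        self._interspace_row = interspace_row

        occupancy = np.full((self.n_row, self.n_col), FREE, dtype=np.int8)
        occupancy[np.ix_(interspace_row, self._channel_cols_mask())] = OBSTACLE
        occupancy.setflags(write=False)
        self.occupancy = occupancy

        self._bin_edges = _bin_edges(self.n_col, 10)
        self._row_third_edges = _third_edges(self.n_row)
        self._col_third_edges = _third_edges(self.n_col)

    def _channel_cols_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_col, dtype=bool)
        mask[self.n_left:self.n_left + self.n_center] = True
        return mask

    # -- basic queries -------------------------------------------------

    def in_grid(self, i: int, j: int) -> bool:
        return 1 <= i <= self.n_row and 1 <= j <= self.n_col

    def is_obstacle(self, i: int, j: int) -> bool:
        return self.occupancy[i - 1, j - 1] == OBSTACLE

    def section_of(self, j: int) -> str:
        """Section ('left' | 'channel' | 'right') of a 1-based column."""
        if not 1 <= j <= self.n_col:
            raise IndexError(f"column {j} outside 1..{self.n_col}")
        if j <= self.n_left:
            return "left"
        if j <= self.n_left + self.n_center:
            return "channel"
        return "right"

    def cell_center(self, i: int, j: int) -> tuple[float, float]:
        """Physical (x, y) center of square (i, j) in um; y increases upward."""
        g = self.geometry
        x = (j - 0.5) * g.dx
        y = self.n_row * g.dy - (i - 0.5) * g.dy
        return x, y

    @cached_property
    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinates as (n_row, n_col) arrays, um."""
        g = self.geometry
        jj, ii = np.meshgrid(np.arange(1, self.n_col + 1), np.arange(1, self.n_row + 1))
        return (jj - 0.5) * g.dx, self.n_row * g.dy - (ii - 0.5) * g.dy

    def section_columns(self, section: str) -> np.ndarray:
        """1-based column indices belonging to a section."""
        starts = {"left": 1, "channel": self.n_left + 1,
                  "right": self.n_left + self.n_center + 1}
        widths = {"left": self.n_left, "channel": self.n_center, "right": self.n_right}
        if section not in starts:
            raise ValueError(f"unknown section {section!r}")
        return np.arange(starts[section], starts[section] + widths[section])

    # -- partitions -----------------------------------------------------

    def bin_index(self, col: int, n_bins: int = 10) -> int:
        """1-based bin id of a 1-based column (see :func:`bin_index`)."""
        if n_bins == 10:
            if not 1 <= col <= self.n_col:
                raise IndexError(f"column {col} outside 1..{self.n_col}")
            return int(np.searchsorted(self._bin_edges, col, side="left")) + 1
        return bin_index(col, self.n_col, n_bins)

    def quadrant_index(self, i: int, j: int) -> int:
        """1-based quadrant id (row-major 3x3, top-left = 1) of square (i, j)."""
        if not self.in_grid(i, j):
            raise IndexError(f"square ({i}, {j}) outside the grid")
        ri = int(np.searchsorted(self._row_third_edges, i, side="left"))
        ci = int(np.searchsorted(self._col_third_edges, j, side="left"))
        return 3 * ri + ci + 1

    # -- cached neighbor tables (movement & diffusion kernels) ----------

    @cached_property
    def free_flat(self) -> np.ndarray:
        """Flat (0-based row-major) indices of free squares."""
        return np.flatnonzero(self.occupancy.ravel() == FREE)

    @cached_property
    def ext_neighborhoods(self) -> list[np.ndarray | None]:
        """Per free square: flat indices of the extended Moore neighborhood.

        Ordered row-major over the 3x3 block (the square itself included);
        obstacle and out-of-grid squares are excluded.  ``None`` for obstacle
        squares.
        """
        occ = self.occupancy
        nbrs: list[np.ndarray | None] = []
        for r in range(self.n_row):
            for c in range(self.n_col):
                if occ[r, c] == OBSTACLE:
                    nbrs.append(None)
                    continue
                idx = []
                for dr in (-1, 0, 1):
                    rr = r + dr
                    if not 0 <= rr < self.n_row:
                        continue
                    for dc in (-1, 0, 1):
                        cc = c + dc
                        if 0 <= cc < self.n_col and occ[rr, cc] == FREE:
                            idx.append(rr * self.n_col + cc)
                nbrs.append(np.asarray(idx, dtype=np.int64))
        return nbrs

    @cached_property
    def diffusion_edges(self) -> list[tuple[tuple[int, int], float, np.ndarray]]:
        """Per Moore offset: (offset, 1/distance, admissible-source mask).

        The mask is True at squares p such that both p and p+offset are free
        and in-grid, i.e. flux p -> p+offset is admissible.
        """
        occ_free = self.occupancy == FREE
        edges = []
        for (di, dj), d in zip(MOORE_OFFSETS, MOORE_DISTANCES):
            mask = np.zeros_like(occ_free)
            src = _shift_slices(self.n_row, self.n_col, di, dj)
            dst = _shift_slices(self.n_row, self.n_col, -di, -dj)
            mask[src] = occ_free[src] & occ_free[dst]
            edges.append(((di, dj), 1.0 / d, mask))
        return edges

    @cached_property
    def outflow_coefficient(self) -> np.ndarray:
        """Sum over admissible neighbors of 1/d_n, per square (0 on obstacles)."""
        coef = np.zeros((self.n_row, self.n_col))
        for _, w, mask in self.diffusion_edges:
            coef += w * mask
        return coef

    # -- export ----------------------------------------------------------

    def export_occupancy(self, path) -> None:
        """Write the occupancy label matrix as CSV for inspection."""
        np.savetxt(path, self.occupancy, fmt="%d", delimiter=",")


def _shift_slices(n_row: int, n_col: int, di: int, dj: int):
    """Index slices selecting squares whose (di, dj)-neighbor is in-grid."""
    rs = slice(max(0, -di), n_row - max(0, di))
    cs = slice(max(0, -dj), n_col - max(0, dj))
    return rs, cs


def build_domain(geom: ChipGeometry) -> ChipDomain:
    """Build the discretized chip domain from a validated geometry.

    Each section width is independently rounded up to whole columns, so the
    modeled width can slightly exceed the physical one (the reference
    geometry yields 57 + 42 + 45 = 144 columns and 121 rows).
    """
    return ChipDomain(geom)
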