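"""Deme lattice geography: land/sea mask, coordinates and neighbour topology.

The simulated world is a rectangular lattice of square demes (100 km on a
side by default).  Each deme is either land or water; population can only
ever occupy land demes.  Both population layers (farmers and pastoralists)
share a single :class:`DemeGrid`.

Conventions
-----------
* A deme is addressed as ``DemeIndex(col, row)``; internally arrays are laid
  out ``[row, col]`` (row-major, row 0 at the map's northern edge).
* Projected coordinates are in metres with the cell ``(col=0, row=0)`` corner
  at the origin: ``col = floor(x / cell_size)``, ``row = floor(y / cell_size)``.
* Neighbourhood is the 4-cell von Neumann neighbourhood restricted to land.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "DemeIndex",
    "DemeGrid",
    "build_grid",
    "coord_to_deme",
    "neighbors",
    "read_mask_text",
    "write_mask_text",
]

#: Column/row offsets of the four von Neumann directions (E, W, S, N in
#: array terms; the order is fixed because migration bookkeeping indexes it).
DIRECTIONS: tuple[tuple[int, int], ...] = ((1, 0), (-1, 0), (0, 1), (0, -1))


class DemeIndex(NamedTuple):
    """Lattice address of one deme."""

    col: int
    row: int


@dataclass(frozen=True)
class DemeGrid:
    """Immutable deme lattice with a land/sea mask.

    Parameters
    ----------
    land_mask
        Boolean array of shape ``(n_rows, n_cols)``; ``True`` marks land.
    cell_size_m
        Edge length of one deme in metres (100 km in the default world).
    """

    land_mask: np.ndarray
    cell_size_m: float = 100_000.0
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        mask = np.asarray(self.land_mask, dtype=bool)
        if mask.ndim != 2 or mask.size == 0:
            raise ValueError("land mask must be a non-empty 2-D raster")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        mask = mask.copy()
        mask.setflags(write=False)
        object.__setattr__(self, "land_mask", mask)

    # -- basic shape -----------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.land_mask.shape[0]

    @property
    def n_cols(self) -> int:
        return self.land_mask.shape[1]

    @property
    def n_land(self) -> int:
        return int(self.land_mask.sum())

    def in_bounds(self, idx: DemeIndex) -> bool:
        return 0 <= idx.col < self.n_cols and 0 <= idx.row < self.n_rows

    def is_land(self, idx: DemeIndex) -> bool:
        return self.in_bounds(idx) and bool(self.land_mask[idx.row, idx.col])

    def cell_center(self, idx: DemeIndex) -> tuple[float, float]:
        """Projected (x, y) of the deme centre in metres."""
        return ((idx.col + 0.5) * self.cell_size_m, (idx.row + 0.5) * self.cell_size_m)

    # -- flattened land-cell indexing (used by the demographic engine) ---
    def _build_cache(self) -> None:
        rows, cols = np.nonzero(self.land_mask)
        land_id = np.full(self.land_mask.shape, -1, dtype=np.int64)
        land_id[rows, cols] = np.arange(rows.size)
        # neighbour land ids per direction, -1 where water or off-map
        neigh = np.full((len(DIRECTIONS), rows.size), -1, dtype=np.int64)
        for d, (dc, dr) in enumerate(DIRECTIONS):
            r2, c2 = rows + dr, cols + dc
            ok = (r2 >= 0) & (r2 < self.n_rows) & (c2 >= 0) & (c2 < self.n_cols)
            vals = np.full(rows.size, -1, dtype=np.int64)
            vals[ok] = land_id[r2[ok], c2[ok]]
            neigh[d] = vals
        self._cache.update(
            land_rows=rows,
            land_cols=cols,
            land_id=land_id,
            neighbor_ids=neigh,
            n_neighbors=(neigh >= 0).sum(axis=0),
        )

    def _cached(self, key: str) -> np.ndarray:
        if key not in self._cache:
            self._build_cache()
        return self._cache[key]

    @property
    def land_rows(self) -> np.ndarray:
        return self._cached("land_rows")

    @property
    def land_cols(self) -> np.ndarray:
        return self._cached("land_cols")

    @property
    def land_id(self) -> np.ndarray:
        """``(n_rows, n_cols)`` array mapping cells to land ids (-1 = water)."""
        return self._cached("land_id")

    @property
    def neighbor_ids(self) -> np.ndarray:
        """``(4, n_land)`` land ids of each land cell's neighbours (-1 = none)."""
        return self._cached("neighbor_ids")

    @property
    def n_neighbors(self) -> np.ndarray:
        return self._cached("n_neighbors")

    def deme_of_land_id(self, land_id: int) -> DemeIndex:
        return DemeIndex(int(self.land_cols[land_id]), int(self.land_rows[land_id]))

    def land_id_of(self, idx: DemeIndex) -> int:
        if not self.is_land(idx):
            raise ValueError(f"deme {idx} is water or out of bounds")
        return int(self.land_id[idx.row, idx.col])


def build_grid(mask_raster, cell_size_m: float = 100_000.0) -> DemeGrid:
    """Construct an immutable :class:`DemeGrid` from a boolean raster.

    Raises
    ------
    ValueError
        If the raster is empty, non-rectangular, or ``cell_size_m <= 0``.
    """
    arr = np.asarray(mask_raster)
    if arr.dtype == object or arr.ndim != 2:
        raise ValueError("mask raster must be rectangular (2-D)")
    return DemeGrid(land_mask=arr.astype(bool), cell_size_m=float(cell_size_m))


def coord_to_deme(x_m: float, y_m: float, grid: DemeGrid, name: str = "") -> DemeIndex:
    """Map a projected coordinate to its deme, falling back to the nearest land cell.

    The cell is ``floor(coord / cell_size)`` on each axis.  If that cell is
    water, the nearest land cell is returned (Euclidean distance between cell
    centres; ties broken by smallest ``(row, col)``), mirroring the practice
    of sampling in the deme closest to the true site.
    """
    if not (0 <= x_m < grid.n_cols * grid.cell_size_m) or not (
        0 <= y_m < grid.n_rows * grid.cell_size_m
    ):
        label = f" for sample {name!r}" if name else ""
        raise ValueError(f"coordinate ({x_m}, {y_m}){label} lies outside the grid extent")
    col = int(np.floor(x_m / grid.cell_size_m))
    row = int(np.floor(y_m / grid.cell_size_m))
    idx = DemeIndex(col, row)
    if grid.is_land(idx):
        return idx
    return nearest_land(idx, grid)


def nearest_land(idx: DemeIndex, grid: DemeGrid) -> DemeIndex:
    """Nearest land deme to ``idx`` by centre-to-centre distance.

    Ties are broken by smallest ``(row, col)`` lexicographic order so the
    fallback is deterministic.
    """
    if grid.n_land == 0:
        raise ValueError("grid has no land cells")
    d2 = (grid.land_cols - idx.col) ** 2 + (grid.land_rows - idx.row) ** 2
    order = np.lexsort((grid.land_cols, grid.land_rows, d2))
    best = order[0]
    return DemeIndex(int(grid.land_cols[best]), int(grid.land_rows[best]))


def neighbors(idx: DemeIndex, grid: DemeGrid) -> set[DemeIndex]:
    """Land cells among the four orthogonal neighbours of a land deme."""
    if not grid.is_land(idx):
        raise ValueError(f"deme {idx} is water or out of bounds")
    out = set()
    for dc, dr in DIRECTIONS:
        cand = DemeIndex(idx.col + dc, idx.row + dr)
        if grid.is_land(cand):
            out.add(cand)
    return out


# -- plain-text raster IO ('1' land, '0' water, one row per line) ---------

def read_mask_text(path_or_lines) -> np.ndarray:
    if isinstance(path_or_lines, (list, tuple)):
        lines = [str(l).strip() for l in path_or_lines]
    else:
        with open(path_or_lines) as fh:
            lines = [l.strip() for l in fh]
    lines = [l for l in lines if l]
    if not lines:
        raise ValueError("empty mask raster")
    widths = {len(l) for l in lines}
    if len(widths) != 1:
        raise ValueError("non-rectangular mask raster")
    return np.array([[ch == "1" for ch in l] for l in lines], dtype=bool)


def write_mask_text(grid: DemeGrid, path) -> None:
    with open(path, "w") as fh:
        for row in grid.land_mask:
            fh.write("".join("1" if v else "0" for v in row) + "\n")
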