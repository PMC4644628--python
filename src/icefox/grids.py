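"""Raster grids for utilization distributions and individual-count surfaces.

The convention throughout the package: ``values[row, col]`` with row 0 the
northernmost row and column 0 the westernmost column; all coordinates are
planar meters in a shared projection; distances use cell centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Tolerance on total probability mass of a normalized UD.
MASS_TOL = 1e-9


@dataclass
class GridGeometry:
    """Registration of a north-up raster: lower-left corner, square cells."""

    xll: float
    yll: float
    cell_size: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GridGeometry):
            return NotImplemented
        return (
            self.nrows == other.nrows
            and self.ncols == other.ncols
            and np.isclose(self.xll, other.xll)
            and np.isclose(self.yll, other.yll)
            and np.isclose(self.cell_size, other.cell_size)
        )

    @property
    def x_centers(self) -> np.ndarray:
        return self.xll + (np.arange(self.ncols) + 0.5) * self.cell_size

    @property
    def y_centers(self) -> np.ndarray:
        """Per-row center y, row 0 northernmost."""
        return self.yll + (self.nrows - np.arange(self.nrows) - 0.5) * self.cell_size

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.xll + (col + 0.5) * self.cell_size,
            self.yll + (self.nrows - row - 0.5) * self.cell_size,
        )

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        col = int(np.floor((x - self.xll) / self.cell_size))
        row = self.nrows - 1 - int(np.floor((y - self.yll) / self.cell_size))
        return row, col

    def contains(self, row: int, col: int) -> bool:
        return 0 <= row < self.nrows and 0 <= col < self.ncols

    @classmethod
    def from_bounds(
        cls, xmin: float, ymin: float, xmax: float, ymax: float, cell_size: float
    ) -> "GridGeometry":
        ncols = max(1, int(np.ceil((xmax - xmin) / cell_size)))
        nrows = max(1, int(np.ceil((ymax - ymin) / cell_size)))
        return cls(xll=xmin, yll=ymin, cell_size=cell_size, nrows=nrows, ncols=ncols)


@dataclass
class UDGrid:
    """A utilization distribution: probability mass per cell."""

    geometry: GridGeometry
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.geometry.nrows, self.geometry.ncols):
            raise ValueError(
                f"values shape {self.values.shape} does not match geometry "
                f"({self.geometry.nrows}, {self.geometry.ncols})"
            )
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("UD values must be finite and non-negative")

    @property
    def total_mass(self) -> float:
        return float(self.values.sum())

    def is_normalized(self, tol: float = 1e-8) -> bool:
        return abs(self.total_mass - 1.0) <= tol

    def normalized(self) -> "UDGrid":
        s = self.total_mass
        if s <= 0:
            raise ValueError("cannot normalize a grid with zero total mass")
        return UDGrid(self.geometry, self.values / s)


def cumulative_contour(ud: UDGrid, p: float) -> np.ndarray:
    """Smallest cell set whose cumulative mass first reaches ``p``.

    Cells are taken in descending density order; exact ties are broken by
    (row, col) lexicographic order so the result is deterministic. Returns a
    boolean mask over the grid. Because the ordering is fixed, contours nest:
    ``contour(p1) <= contour(p2)`` whenever ``p1 < p2``.
    """
    if not 0 < p < 1:
        raise ValueError("contour level p must be in (0, 1)")
    if not ud.is_normalized():
        raise ValueError("cumulative_contour requires a normalized UD")
    flat = ud.values.ravel()
    # stable sort on -value; ravel order is already (row, col) lexicographic
    order = np.argsort(-flat, kind="stable")
    csum = np.cumsum(flat[order])
    k = int(np.searchsorted(csum, p, side="left")) + 1
    k = min(k, flat.size)
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(ud.values.shape)


def mask_cells(mask: np.ndarray) -> set[tuple[int, int]]:
    """Boolean cell mask -> set of (row, col) indices."""
    rows, cols = np.nonzero(mask)
    return set(zip(rows.tolist(), cols.tolist()))
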