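"""Regular raster grids: cell-registered, north-west origin, row-major.

Row 0 is the northernmost row; values are attributed to cell centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GridSpec:
    """Definition of a regular raster grid in projected meters."""

    xll: float
    yll: float
    cellsize: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.cellsize <= 0 or self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have positive cell size and dimensions")

    @classmethod
    def from_extent(cls, width: float, height: float, cellsize: float,
                    xll: float = 0.0, yll: float = 0.0) -> "GridSpec":
        ncols = max(1, int(round(width / cellsize)))
        nrows = max(1, int(round(height / cellsize)))
        return cls(xll=xll, yll=yll, cellsize=cellsize, nrows=nrows, ncols=ncols)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    def x_centers(self) -> np.ndarray:
        return self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize

    def y_centers(self) -> np.ndarray:
        """Cell-center y for each row, row 0 = north."""
        return self.yll + (self.nrows - np.arange(self.nrows) - 0.5) * self.cellsize

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        X, Y = np.meshgrid(self.x_centers(), self.y_centers())
        return X, Y

    def cell_centers(self) -> np.ndarray:
        """All cell centers as an (n_cells, 2) array in row-major order."""
        X, Y = self.center_mesh()
        return np.column_stack([X.ravel(), Y.ravel()])

    def point_to_rowcol(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Containing cell of each point, clipped to the grid."""
        col = np.clip(((np.asarray(x, float) - self.xll) / self.cellsize).astype(int), 0, self.ncols - 1)
        row_s = np.clip(((np.asarray(y, float) - self.yll) / self.cellsize).astype(int), 0, self.nrows - 1)
        return self.nrows - 1 - row_s, col

    def point_to_index(self, x, y) -> np.ndarray:
        r, c = self.point_to_rowcol(x, y)
        return r * self.ncols + c

    def bilinear(self, values: np.ndarray, x, y) -> np.ndarray:
        """Bilinear interpolation of a cell-center raster at arbitrary points.

        Coordinates outside the center lattice are clamped to the edge.
        """
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        gx = np.clip((x - self.xll) / self.cellsize - 0.5, 0.0, self.ncols - 1.0)
        # y axis: row index grows southwards
        gy = np.clip((self.yll + self.nrows * self.cellsize - y) / self.cellsize - 0.5,
                     0.0, self.nrows - 1.0)
        c0 = np.clip(np.floor(gx).astype(int), 0, self.ncols - 2) if self.ncols > 1 else np.zeros_like(gx, int)
        r0 = np.clip(np.floor(gy).astype(int), 0, self.nrows - 2) if self.nrows > 1 else np.zeros_like(gy, int)
        fx = gx - c0
        fy = gy - r0
        c1 = np.minimum(c0 + 1, self.ncols - 1)
        r1 = np.minimum(r0 + 1, self.nrows - 1)
        v = (values[r0, c0] * (1 - fx) * (1 - fy)
             + values[r0, c1] * fx * (1 - fy)
             + values[r1, c0] * (1 - fx) * fy
             + values[r1, c1] * fx * fy)
        return v
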