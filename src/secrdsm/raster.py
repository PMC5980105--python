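"""Minimal planar raster container used for landscape covariates.

Coordinates are projected kilometres. Row ``i`` of ``values`` covers the band
``y0 + i*resolution .. y0 + (i+1)*resolution`` (row 0 is the *southern* edge);
cell centres sit at half-resolution offsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Raster:
    values: np.ndarray  # (ny, nx) float array; NaN marks missing
    x0: float
    y0: float
    resolution: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.resolution <= 0:
            raise ValueError("raster resolution must be positive")

    @property
    def ny(self) -> int:
        return self.values.shape[0]

    @property
    def nx(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the covered rectangle."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.nx * self.resolution,
            self.y0 + self.ny * self.resolution,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.x0 + (np.arange(self.nx) + 0.5) * self.resolution
        ys = self.y0 + (np.arange(self.ny) + 0.5) * self.resolution
        return xs, ys

    def center_grid(self) -> np.ndarray:
        """(ny*nx, 2) array of every cell-centre coordinate."""
        xs, ys = self.cell_centers()
        xx, yy = np.meshgrid(xs, ys)
        return np.column_stack([xx.ravel(), yy.ravel()])

    def sample(self, x, y):
        """Raster value at the cell containing each (x, y); NaN outside."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        j = np.floor((x - self.x0) / self.resolution).astype(int)
        i = np.floor((y - self.y0) / self.resolution).astype(int)
        out = np.full(np.broadcast(x, y).shape, np.nan)
        ok = (i >= 0) & (i < self.ny) & (j >= 0) & (j < self.nx)
        out[ok] = self.values[i[ok], j[ok]]
        return out if out.ndim else float(out)
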