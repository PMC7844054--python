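"""Resampling, polarity-aware min-max standardization, and fishnet
extraction to an observation matrix.

All fifteen indicator surfaces are brought to a common 1-km analysis
grid, scaled to [0, 1], and stacked; the matrix of valid cells x
indicators ("fishnet" values) feeds both index systems.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .core_model import GridSpec, RasterLayer
from .errors import DegenerateLayerError, StructuralError

__all__ = [
    "resample_bilinear",
    "minmax_normalize",
    "ObservationMatrix",
    "build_matrix",
]


def resample_bilinear(layer: RasterLayer, target: GridSpec) -> RasterLayer:
    """Bilinear resampling of a layer onto a target grid.

    Each target cell center is interpolated from the four surrounding
    source cell centers.  Target cells whose four-point neighborhood
    touches a nodata source cell, or which fall outside the source
    center extent, come out nodata (NaN).
    """
    src = layer.grid
    if src == target and layer.values.shape == target.shape:
        return RasterLayer(target, layer.name, layer.values.copy(), layer.units)

    tx, ty = target.cell_centers()
    # fractional source array indices of the target centers
    col = (tx - src.x_origin) / src.cell_size - 0.5
    row = (src.y_origin + src.n_rows * src.cell_size - ty) / src.cell_size - 0.5

    inside = (
        (col >= 0.0)
        & (col <= src.n_cols - 1)
        & (row >= 0.0)
        & (row <= src.n_rows - 1)
    )
    if not inside.any():
        raise StructuralError(
            f"layer {layer.name!r}: source and target extents are disjoint"
        )
    # order-1 spline is exactly the 4-point bilinear formula; NaNs in the
    # source propagate to every target cell whose stencil touches them
    out = map_coordinates(
        layer.values, [row, col], order=1, mode="nearest", cval=np.nan
    )
    out[~inside] = np.nan
    return RasterLayer(target, layer.name, out, layer.units)


def minmax_normalize(layer: RasterLayer, polarity: str = "direct") -> RasterLayer:
    """Scale a layer to [0, 1] by its own valid min/max.

    direct:  V = (v - vmin) / (vmax - vmin)
    inverse: V = (vmax - v) / (vmax - vmin)  (= 1 - direct)

    The min and max are taken over the valid cells of this layer (the
    study mask), not over theoretical ranges.  A constant layer cannot be
    scaled (zero range) and is an error naming the indicator.
    """
    if polarity not in ("direct", "inverse"):
        raise StructuralError(f"unknown polarity {polarity!r}")
    v = layer.values
    vmin = np.nanmin(v) if np.isfinite(v).any() else np.nan
    vmax = np.nanmax(v) if np.isfinite(v).any() else np.nan
    if not np.isfinite(vmin) or vmax == vmin:
        raise DegenerateLayerError(
            f"layer {layer.name!r} is constant or empty; min-max scaling undefined"
        )
    scaled = (v - vmin) / (vmax - vmin)
    if polarity == "inverse":
        scaled = 1.0 - scaled
    return RasterLayer(layer.grid, layer.name, scaled, "standardized")


@dataclass
class ObservationMatrix:
    """Valid-cell x indicator table extracted from the stacked rasters.

    A cell enters the matrix only if it is valid in *every* layer
    (intersection mask).  ``cells`` holds the (row, col) index of each
    matrix row, so any per-cell vector can be painted back onto the grid.
    """

    grid: GridSpec
    cells: np.ndarray  # (n_cells, 2) int array of (row, col)
    table: pd.DataFrame  # n_cells x n_indicators

    @property
    def names(self) -> list[str]:
        return list(self.table.columns)

    @property
    def n_cells(self) -> int:
        return len(self.table)

    def to_raster(self, vector: np.ndarray, name: str, units: str = "") -> RasterLayer:
        """Paint a per-valid-cell vector back onto the grid (NaN elsewhere)."""
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (self.n_cells,):
            raise StructuralError(
                f"vector length {vector.shape} does not match {self.n_cells} cells"
            )
        out = np.full(self.grid.shape, np.nan)
        out[self.cells[:, 0], self.cells[:, 1]] = vector
        return RasterLayer(self.grid, name, out, units)

    def column_raster(self, name: str) -> RasterLayer:
        return self.to_raster(self.table[name].to_numpy(), name)


def build_matrix(layers: Sequence[RasterLayer], order: Sequence[str] | None = None) -> ObservationMatrix:
    """Stack standardized layers into an observation matrix.

    Column order follows ``order`` when given (the config's indicator
    order), otherwise the layer sequence; the result is independent of
    file load order when ``order`` is supplied.
    """
    if not layers:
        raise StructuralError("no layers to stack")
    grid = layers[0].grid
    by_name = {lyr.name: lyr for lyr in layers}
    names = list(order) if order is not None else [lyr.name for lyr in layers]
    missing = set(names) - set(by_name)
    if missing:
        raise StructuralError(f"layers missing from stack: {sorted(missing)}")
    for lyr in layers:
        if lyr.grid != grid:
            raise StructuralError(
                f"layer {lyr.name!r} grid differs from {layers[0].name!r}"
            )
    stack = np.stack([by_name[n].values for n in names])  # (p, rows, cols)
    mask = np.all(np.isfinite(stack), axis=0)
    cells = np.argwhere(mask)
    table = pd.DataFrame(
        {n: stack[i][mask] for i, n in enumerate(names)}
    )
    return ObservationMatrix(grid, cells, table)
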