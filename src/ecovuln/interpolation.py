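"""Inverse distance weighted (IDW) interpolation of station data.

The estimate at a target point is the distance-decay weighted average of
the values at the N nearest stations,

    z0 = sum_i z_i d_i^(-n) / sum_i d_i^(-n),

with n the power (distance exponent) and d_i planar Euclidean distances.
Weights are positive and normalized, so every estimate is a convex
combination of station values (bounded by their min and max).  A target
coinciding with a station (distance < eps) returns that station's value
exactly — the limit of the formula as d -> 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .core_model import GridSpec, RasterLayer
from .errors import StructuralError

__all__ = ["StationSet", "IdwParams", "idw_estimate", "idw_surface"]

#: Distance below which a target is considered to coincide with a station.
COINCIDENCE_EPS = 1e-9


@dataclass
class StationSet:
    """Irregular sample points (x, y, value) for one indicator."""

    name: str
    x: np.ndarray
    y: np.ndarray
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not (self.x.shape == self.y.shape == self.values.shape):
            raise StructuralError(f"stations {self.name!r}: x, y, value lengths differ")
        if self.x.size < 1:
            raise StructuralError(f"stations {self.name!r}: no stations")
        if not np.all(np.isfinite(self.values)):
            raise StructuralError(f"stations {self.name!r}: non-finite values")
        coords = np.column_stack([self.x, self.y])
        if len(np.unique(coords, axis=0)) != len(coords):
            raise StructuralError(f"stations {self.name!r}: duplicate coordinates")

    def __len__(self) -> int:
        return self.x.size

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass(frozen=True)
class IdwParams:
    """IDW tuning: distance exponent and neighbor count.

    ``power`` defaults to 2 and ``neighbors`` to 12 — the de-facto GIS
    defaults.  ``neighbors=None`` uses every station.  Stations tied with
    the N-th nearest distance are all included, which makes the cutoff
    deterministic and independent of input order.
    """

    power: float = 2.0
    neighbors: int | None = 12

    def __post_init__(self) -> None:
        if self.power <= 0:
            raise StructuralError(f"IDW power must be > 0, got {self.power}")
        if self.neighbors is not None and self.neighbors < 1:
            raise StructuralError(f"IDW neighbors must be >= 1, got {self.neighbors}")


def _idw_points(
    stations: StationSet, targets: np.ndarray, params: IdwParams
) -> np.ndarray:
    """Vectorized IDW at an (m, 2) array of target coordinates."""
    d = cdist(targets, stations.coords)  # (m, k)
    z = stations.values
    k = len(stations)
    n_use = k if params.neighbors is None else min(params.neighbors, k)

    if n_use < k:
        # distance of the N-th nearest station per target; include ties
        kth = np.partition(d, n_use - 1, axis=1)[:, n_use - 1]
        sel = d <= kth[:, None] * (1.0 + 1e-12)
    else:
        sel = np.ones_like(d, dtype=bool)

    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        w = np.where(sel, d, np.inf) ** (-params.power)
        # rows with a coinciding station produce inf/inf here; they are
        # overwritten with the exact station value below
        est = (w @ z) / w.sum(axis=1)

    # exact value at coinciding stations (limit of the formula)
    hit_t, hit_s = np.nonzero(d < COINCIDENCE_EPS)
    est[hit_t] = z[hit_s]
    return est


def idw_estimate(
    stations: StationSet, x: float, y: float, params: IdwParams = IdwParams()
) -> float:
    """IDW estimate at a single point."""
    return float(_idw_points(stations, np.array([[x, y]], dtype=float), params)[0])


def idw_surface(
    stations: StationSet,
    grid: GridSpec,
    params: IdwParams = IdwParams(),
    mask: np.ndarray | None = None,
) -> RasterLayer:
    """IDW estimate at every (valid) cell center of the analysis grid.

    Parameters
    ----------
    mask
        Optional boolean validity mask; cells outside it become NaN.
    """
    gx, gy = grid.cell_centers()
    targets = np.column_stack([gx.ravel(), gy.ravel()])
    if mask is not None:
        if mask.shape != grid.shape:
            raise StructuralError("mask shape does not match grid")
        flat = mask.ravel()
        out = np.full(targets.shape[0], np.nan)
        out[flat] = _idw_points(stations, targets[flat], params)
    else:
        out = _idw_points(stations, targets, params)
    return RasterLayer(grid, stations.name, out.reshape(grid.shape), stations.units)
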