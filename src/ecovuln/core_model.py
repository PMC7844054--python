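"""Grid-aligned raster data model, the five-class vulnerability scheme,
and area accounting.

Conventions fixed here and used by every other module:

* Row 0 is the **top** (northernmost) row of the raster; ``(x_origin,
  y_origin)`` is the lower-left corner of the grid, as in the ESRI ASCII
  grid header.
* In memory, invalid cells are ``NaN``; the ``nodata_value`` sentinel
  exists only on disk (see :mod:`ecovuln.io_gis`).
* Cell size is declared in meters; areas are reported in km², converted
  exactly as ``cell_size**2 / 1e6``.
* The ecological vulnerability index (EVI) lives on [0, 1] and is
  partitioned into five equal-width classes, Potential (most stable)
  through High (most vulnerable).  Intervals are half-open
  ``[b_i, b_{i+1})`` with 1.0 assigned to High, so every value in [0, 1]
  receives exactly one class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import RangeError, StructuralError

__all__ = [
    "GridSpec",
    "RasterLayer",
    "ClassificationScheme",
    "ClassifiedSurface",
    "AreaReport",
    "classify_value",
    "classify_surface",
    "area_by_class",
    "compare_reports",
    "DEFAULT_SCHEME",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the analysis grid.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; row 0 is the top (north) row.
    x_origin, y_origin
        Map coordinates of the lower-left corner, in the declared
        (projected) unit — meters by default.
    cell_size
        Edge length of a square cell, same unit as the origin.
    nodata_value
        Sentinel written to disk for invalid cells.
    """

    n_rows: int
    n_cols: int
    x_origin: float = 0.0
    y_origin: float = 0.0
    cell_size: float = 1000.0
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise StructuralError(
                f"grid must have positive dimensions, got {self.n_rows}x{self.n_cols}"
            )
        if self.cell_size <= 0:
            raise StructuralError(f"cell_size must be > 0, got {self.cell_size}")

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Map coordinates of the center of cell ``(row, col)``."""
        x = self.x_origin + (col + 0.5) * self.cell_size
        y = self.y_origin + (self.n_rows - 1 - row + 0.5) * self.cell_size
        return x, y

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) center-coordinate arrays, each shaped (n_rows, n_cols)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.x_origin + (cols + 0.5) * self.cell_size
        y = self.y_origin + (self.n_rows - 1 - rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size**2 / 1e6

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)


@dataclass
class RasterLayer:
    """A named indicator surface on an analysis grid.

    ``values`` is an ``n_rows x n_cols`` float array; invalid cells are
    NaN and are excluded from every statistic.
    """

    grid: GridSpec
    name: str
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise StructuralError(
                f"layer {self.name!r}: values shape {self.values.shape} "
                f"does not match grid {self.grid.shape}"
            )

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    def with_values(self, values: np.ndarray, name: str | None = None) -> "RasterLayer":
        return RasterLayer(self.grid, name or self.name, values, self.units)


#: Class labels in increasing order of vulnerability.
CLASS_LABELS = ("Potential", "Slight", "Low", "Moderate", "High")

#: Equal-interval ranks as conventionally printed (two decimals).
CLASS_RANKS = ("0.00-0.20", "0.21-0.40", "0.41-0.60", "0.61-0.80", "0.81-1.00")


@dataclass(frozen=True)
class ClassificationScheme:
    """Five equal-interval vulnerability classes on [0, 1]."""

    labels: tuple[str, ...] = CLASS_LABELS
    boundaries: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries)
        if len(self.labels) != 5 or len(self.boundaries) != 6:
            raise StructuralError("scheme must define exactly 5 classes")
        if not np.all(np.diff(b) > 0):
            raise StructuralError("boundaries must be strictly increasing")
        if b[0] != 0.0 or b[-1] != 1.0:
            raise StructuralError("boundaries must cover [0, 1] exactly")


DEFAULT_SCHEME = ClassificationScheme()


def classify_value(v: float, scheme: ClassificationScheme = DEFAULT_SCHEME) -> str:
    """Class label of a single EVI value.

    Intervals are half-open ``[b_i, b_{i+1})``; 1.0 is top-inclusive and
    returns the highest class.
    """
    if not (0.0 <= v <= 1.0):
        raise RangeError(f"EVI value {v!r} outside [0, 1]")
    idx = int(np.searchsorted(scheme.boundaries, v, side="right")) - 1
    idx = min(idx, len(scheme.labels) - 1)  # v == 1.0 -> top class
    return scheme.labels[idx]


@dataclass
class ClassifiedSurface:
    """Per-cell class index (0..4) on a grid; invalid cells are -1."""

    grid: GridSpec
    class_index: np.ndarray
    scheme: ClassificationScheme = field(default_factory=ClassificationScheme)

    @property
    def valid_mask(self) -> np.ndarray:
        return self.class_index >= 0

    def labels(self) -> np.ndarray:
        """Object array of labels; None on invalid cells."""
        out = np.full(self.grid.shape, None, dtype=object)
        m = self.valid_mask
        out[m] = np.asarray(self.scheme.labels, dtype=object)[self.class_index[m]]
        return out


def classify_surface(
    evi: RasterLayer, scheme: ClassificationScheme = DEFAULT_SCHEME
) -> ClassifiedSurface:
    """Cell-wise classification of an EVI surface.

    Invalid (NaN) cells stay unclassified; any valid cell outside [0, 1]
    is an error naming the cell.
    """
    vals = evi.values
    mask = np.isfinite(vals)
    bad = mask & ((vals < 0.0) | (vals > 1.0))
    if np.any(bad):
        r, c = map(int, np.argwhere(bad)[0])
        raise RangeError(
            f"layer {evi.name!r}: cell ({r}, {c}) value {vals[r, c]!r} outside [0, 1]"
        )
    idx = np.full(evi.grid.shape, -1, dtype=int)
    b = np.asarray(scheme.boundaries)
    idx[mask] = np.clip(
        np.searchsorted(b, vals[mask], side="right") - 1, 0, len(scheme.labels) - 1
    )
    return ClassifiedSurface(evi.grid, idx, scheme)


@dataclass
class AreaReport:
    """Per-class areas in km² plus the total valid area."""

    scheme: ClassificationScheme
    class_areas_km2: dict[str, float]

    @property
    def total_km2(self) -> float:
        return float(sum(self.class_areas_km2.values()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": CLASS_RANKS,
                "classification": list(self.scheme.labels),
                "area_km2": [self.class_areas_km2[lb] for lb in self.scheme.labels],
            }
        )

    @classmethod
    def from_areas(
        cls, areas: Sequence[float], scheme: ClassificationScheme = DEFAULT_SCHEME
    ) -> "AreaReport":
        """Build a report from five areas given in class order."""
        if len(areas) != len(scheme.labels):
            raise StructuralError("need one area per class")
        return cls(scheme, {lb: float(a) for lb, a in zip(scheme.labels, areas)})


def area_by_class(cs: ClassifiedSurface) -> AreaReport:
    """Count cells per class and convert to km².

    Conservation holds exactly: the class areas sum to the total valid
    area (cell count x cell area).
    """
    counts = np.bincount(
        cs.class_index[cs.valid_mask], minlength=len(cs.scheme.labels)
    )
    a = cs.grid.cell_area_km2
    return AreaReport(
        cs.scheme, {lb: float(n * a) for lb, n in zip(cs.scheme.labels, counts)}
    )


def compare_reports(a: AreaReport, b: AreaReport) -> pd.DataFrame:
    """Per-class difference table ``b − a`` with Inc/Reg/Stable tags.

    Mirrors the observed-vs-enhanced area comparison: positive
    differences are tagged ``Inc`` (increase), negative ``Reg``
    (regression), zero ``Stable``.
    """
    if a.scheme != b.scheme:
        raise StructuralError("area reports use different classification schemes")
    rows = []
    for rank, lb in zip(CLASS_RANKS, a.scheme.labels):
        av, bv = a.class_areas_km2[lb], b.class_areas_km2[lb]
        d = bv - av
        qual = "Inc" if d > 0 else ("Reg" if d < 0 else "Stable")
        rows.append((rank, lb, av, bv, d, qual))
    return pd.DataFrame(
        rows,
        columns=["rank", "classification", "obs_km2", "enh_km2", "dif_km2", "qualification"],
    )
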