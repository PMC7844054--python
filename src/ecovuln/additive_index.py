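"""Additive (IPCC-style) EVI: exposure, sensitivity and adaptation
component indices and their weighted combination.

Each component index is the plain arithmetic mean of its standardized
member indicators; the vulnerability index is a convex combination of
the three components (equal thirds by default), so it stays in [0, 1]
by construction and needs no rescaling.

Default grouping of the fifteen indicators: exposure = {temperature,
rainfall, humidity, sunlight, flood, drought}; sensitivity =
{population, density, elevation, slope, ndvi, carbon, houses};
adaptation = {gdp, fire}.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core_model import RasterLayer
from .composite_pca import WeightVector
from .errors import StructuralError

__all__ = ["IndicatorGrouping", "DEFAULT_GROUPING", "component_index", "additive_evi", "EQUAL_WEIGHTS"]

COMPONENTS = ("exposure", "sensitivity", "adaptation")


@dataclass(frozen=True)
class IndicatorGrouping:
    """Partition of the indicator set into the three components."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {n: g for n, g in self.mapping.items() if g not in COMPONENTS}
        if bad:
            raise StructuralError(f"unknown components: {bad}")

    def members(self, component: str) -> list[str]:
        if component not in COMPONENTS:
            raise StructuralError(f"unknown component {component!r}")
        return [n for n, g in self.mapping.items() if g == component]


DEFAULT_GROUPING = IndicatorGrouping(
    {
        "temperature": "exposure",
        "rainfall": "exposure",
        "humidity": "exposure",
        "sunlight": "exposure",
        "flood": "exposure",
        "drought": "exposure",
        "population": "sensitivity",
        "density": "sensitivity",
        "elevation": "sensitivity",
        "slope": "sensitivity",
        "ndvi": "sensitivity",
        "carbon": "sensitivity",
        "houses": "sensitivity",
        "gdp": "adaptation",
        "fire": "adaptation",
    }
)


def equal_weights() -> WeightVector:
    """Exact thirds for (exposure, sensitivity, adaptation)."""
    return WeightVector(np.array([1, 1, 1]) / 3.0, provenance="user", names=COMPONENTS)


EQUAL_WEIGHTS = equal_weights


def component_index(
    layers: Mapping[str, RasterLayer] | Sequence[RasterLayer],
    members: Sequence[str],
    name: str,
) -> RasterLayer:
    """Cell-wise arithmetic mean of a component's standardized layers."""
    if not members:
        raise StructuralError(f"component {name!r} has no indicators")
    if not isinstance(layers, Mapping):
        layers = {lyr.name: lyr for lyr in layers}
    missing = [m for m in members if m not in layers]
    if missing:
        raise StructuralError(f"component {name!r}: missing layers {missing}")
    grid = layers[members[0]].grid
    for m in members:
        if layers[m].grid != grid:
            raise StructuralError(f"component {name!r}: grid mismatch at {m!r}")
    stack = np.stack([layers[m].values for m in members])
    return RasterLayer(grid, name, stack.mean(axis=0), "standardized")


def additive_evi(
    exposure: RasterLayer,
    sensitivity: RasterLayer,
    adaptation: RasterLayer,
    weights: WeightVector | None = None,
    name: str = "evi_ad",
) -> RasterLayer:
    """Weighted sum of the three component surfaces.

    With the default equal weights this is the plain mean.  Any
    nonnegative weights summing to one keep the result in [0, 1].
    """
    if weights is None:
        weights = equal_weights()
    if len(weights) != 3:
        raise StructuralError("additive weights must have length 3 (E, S, A)")
    grid = exposure.grid
    if sensitivity.grid != grid or adaptation.grid != grid:
        raise StructuralError("component grids do not match")
    w = weights.weights
    vals = w[0] * exposure.values + w[1] * sensitivity.values + w[2] * adaptation.values
    return RasterLayer(grid, name, vals, "EVI")
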