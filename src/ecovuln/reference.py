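"""Published reference figures from the Benin 2016 hybrid EVI assessment.

These constants are the printed outputs of the original country-scale
study (whose raw rasters were never deposited).  They serve two roles:

* inputs to the arithmetic stages that operate on published tables —
  variance-ratio weighting, component retention, and observed-vs-enhanced
  area comparison;
* fixtures for report formatting, clearly not re-derived by this package
  (the underlying station and raster data are unavailable).
"""

from __future__ import annotations

from .core_model import AreaReport

#: Eigenvalues of the correlation matrix for the six retained principal
#: components (of p = 15 indicators), as printed.
RETAINED_EIGENVALUES = (5.479, 1.951, 1.518, 1.269, 1.138, 0.937)

#: Printed per-component variance percentages (100 * eigenvalue / 15) for
#: the six retained components; cumulative 81.948 %.
RETAINED_VARIANCE_PCT = (36.525, 13.009, 10.117, 8.462, 7.587, 6.248)

#: Observed composite weights (variance ratios of the retained
#: eigenvalues) and their regression-enhanced counterparts, per component.
COMPOSITE_WEIGHTS_OBSERVED = (0.446, 0.159, 0.123, 0.103, 0.093, 0.076)
COMPOSITE_WEIGHTS_ENHANCED = (0.730, 0.050, 0.200, 0.010, 0.010, 0.000)

#: Exposure / sensitivity / adaptation weights for the additive system.
#: The observed row is display rounding of exact thirds.
ADDITIVE_WEIGHTS_OBSERVED = (0.340, 0.330, 0.330)
ADDITIVE_WEIGHTS_ENHANCED = (0.010, 0.190, 0.800)

#: Observed and enhanced class areas (km²), in class order Potential,
#: Slight, Low, Moderate, High.
COMPOSITE_AREAS_OBSERVED = (48_600.0, 46_314.0, 12_270.0, 3_849.0, 3_729.0)
COMPOSITE_AREAS_ENHANCED = (60_269.0, 25_984.0, 11_669.0, 12_030.0, 4_812.0)
ADDITIVE_AREAS_OBSERVED = (36_450.0, 22_736.0, 40_540.0, 12_030.0, 3_007.0)
ADDITIVE_AREAS_ENHANCED = (32_119.0, 22_255.0, 27_548.0, 25_864.0, 6_977.0)

#: Country area, km² (the five observed composite areas sum to 114,762).
COUNTRY_AREA_KM2 = 114_763.0

#: Average per-capita densities (inhabitants per km²) of the least- and
#: most-dense provinces in the source statistics: Borgou vs Littoral.
DENSITY_BORGOU = 35.909
DENSITY_LITTORAL = 8003.636

#: Global Moran's I of the two observed EVI surfaces as published
#: (fixtures only; they depend on the undeposited rasters).
MORANS_I_COMPOSITE = 0.955256
MORANS_I_ADDITIVE = 0.989222


def composite_reports() -> tuple[AreaReport, AreaReport]:
    """Observed and enhanced composite-system area reports."""
    return (
        AreaReport.from_areas(COMPOSITE_AREAS_OBSERVED),
        AreaReport.from_areas(COMPOSITE_AREAS_ENHANCED),
    )


def additive_reports() -> tuple[AreaReport, AreaReport]:
    """Observed and enhanced additive-system area reports."""
    return (
        AreaReport.from_areas(ADDITIVE_AREAS_OBSERVED),
        AreaReport.from_areas(ADDITIVE_AREAS_ENHANCED),
    )
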