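"""Regression-based weight enhancement.

The observed EVI is regressed on its own components (principal-component
scores for the composite system; exposure / sensitivity / adaptation for
the additive system) by exhaustive best-subsets OLS.  The winning
subset's coefficients are clamped at zero and normalized into a new
weight vector, the index is recomputed with those weights, reclassified,
and the observed-vs-enhanced class areas are compared.

This is a precise, reproducible re-reading of automatic linear modeling
model building (ALMMB): every nonempty predictor subset is fit (2^p - 1
fits; exhaustive enumeration is cheap for p <= 15), ranked by adjusted
R² (or AIC/BIC), with ties broken toward the smaller subset and then
lexicographically, so the selection is deterministic given input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .core_model import (
    ClassificationScheme,
    DEFAULT_SCHEME,
    RasterLayer,
    area_by_class,
    classify_surface,
    compare_reports,
)
from .composite_pca import WeightVector, orient_to_indicators, rescale_unit
from .additive_index import additive_evi
from .errors import RankError, StructuralError
from .preprocess import ObservationMatrix
from .spatial_stats import LinearFit, linear_fit

__all__ = ["BestSubsetsResult", "best_subsets", "reweight", "enhanced_evi"]


@dataclass
class BestSubsetsResult:
    """Winning subset, its fit, and the full ranking table."""

    subset: tuple[str, ...]
    fit: LinearFit
    criterion: str
    ranking: pd.DataFrame  # one row per evaluated subset, best first


def _criterion_value(fit: LinearFit, criterion: str, n: int, sse: float, k: int) -> float:
    if criterion == "adjr2":
        return fit.r2_adj
    # information criteria: larger-is-better convention via negation
    sigma2 = max(sse / n, 1e-300)
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    n_par = k + 2  # coefficients + intercept + variance
    if criterion == "aic":
        return -(2 * n_par - 2 * ll)
    if criterion == "bic":
        return -(np.log(n) * n_par - 2 * ll)
    raise StructuralError(f"unknown criterion {criterion!r}")


def best_subsets(
    y: np.ndarray, predictors: pd.DataFrame, criterion: str = "adjr2"
) -> BestSubsetsResult:
    """Exhaustive best-subsets OLS over every nonempty predictor subset.

    Rank-deficient subsets are skipped with a warning row; if every
    subset is skipped the search fails.  The winner maximizes the
    criterion; ties break toward fewer predictors, then lexicographic
    column order.
    """
    names = list(predictors.columns)
    if len(names) > 15:
        raise StructuralError(
            f"{len(names)} predictors; exhaustive enumeration capped at 15"
        )
    y = np.asarray(y, dtype=float)
    rows = []
    best = None
    for size in range(1, len(names) + 1):
        for combo in combinations(range(len(names)), size):
            sub = [names[j] for j in combo]
            try:
                fit = linear_fit(y, predictors[sub])
            except RankError:
                rows.append((tuple(sub), size, np.nan, np.nan, "skipped: rank-deficient"))
                continue
            resid_sse = (1.0 - fit.r2) * float(((y - y.mean()) ** 2).sum())
            value = _criterion_value(fit, criterion, len(y), resid_sse, size)
            rows.append((tuple(sub), size, fit.r2, value, ""))
            # enumeration order is size-ascending then lexicographic, so a
            # strict improvement implements the documented tie-break
            if best is None or value > best[0]:
                best = (value, tuple(sub), fit)
    if best is None:
        raise RankError("every predictor subset was rank-deficient")
    ranking = pd.DataFrame(
        rows, columns=["subset", "size", "r2", "criterion_value", "note"]
    ).sort_values("criterion_value", ascending=False, kind="stable", na_position="last")
    return BestSubsetsResult(best[1], best[2], criterion, ranking.reset_index(drop=True))


def reweight(
    coefficients: Sequence[float] | pd.Series,
    component_names: Sequence[str] | None = None,
    selected: Sequence[str] | None = None,
) -> WeightVector:
    """Clamp-and-normalize regression coefficients into weights.

    Negative coefficients are clamped to zero; components excluded from
    the selected subset get weight zero; the rest are normalized to sum
    one.  All-nonpositive coefficients admit no interpretable weighting
    and are an error.  Idempotent: reweighting a weight vector returns
    it unchanged.
    """
    if isinstance(coefficients, pd.Series):
        coefficients = coefficients.drop(index="intercept", errors="ignore")
        if component_names is None and selected is None:
            selected = list(coefficients.index)
        coefficients = coefficients.to_numpy()
    c = np.asarray(coefficients, dtype=float)
    if component_names is not None:
        full = np.zeros(len(component_names))
        sel = list(selected) if selected is not None else list(component_names)
        for name, value in zip(sel, c):
            full[list(component_names).index(name)] = value
        c = full
        names = tuple(component_names)
    else:
        names = tuple(selected) if selected is not None else None
    clamped = np.clip(c, 0.0, None)
    total = clamped.sum()
    if total <= 0:
        raise StructuralError("all coefficients nonpositive; no interpretable weights")
    w = clamped / total
    w[np.argmax(w)] += 1.0 - w.sum()  # exact unit sum
    return WeightVector(w, provenance="enhanced", names=names)


def enhanced_evi(
    system: str,
    weights: WeightVector,
    *,
    matrix: ObservationMatrix | None = None,
    scores: np.ndarray | None = None,
    components: Sequence[RasterLayer] | None = None,
    observed: RasterLayer | None = None,
    scheme: ClassificationScheme = DEFAULT_SCHEME,
) -> tuple[RasterLayer, pd.DataFrame | None]:
    """Recompute an EVI under new weights and compare class areas.

    ``system`` is ``"pca"`` (needs ``scores`` + ``matrix``; weighted
    component scores, then min-max rescale) or ``"additive"`` (needs the
    three ``components``; weighted mean).  When the ``observed`` surface
    is given, returns the observed-vs-enhanced area comparison table.
    """
    if system == "pca":
        if scores is None or matrix is None:
            raise StructuralError("pca branch needs scores and matrix")
        raw = orient_to_indicators(scores[:, : len(weights)] @ weights.weights, matrix)
        surface = matrix.to_raster(rescale_unit(raw, "evi_pca_enh"), "evi_pca_enh")
    elif system == "additive":
        if components is None or len(components) != 3:
            raise StructuralError("additive branch needs the three component layers")
        surface = additive_evi(*components, weights=weights, name="evi_ad_enh")
    else:
        raise StructuralError(f"unknown system {system!r}")

    comparison = None
    if observed is not None:
        obs_report = area_by_class(classify_surface(observed, scheme))
        enh_report = area_by_class(classify_surface(surface, scheme))
        comparison = compare_reports(obs_report, enh_report)
    return surface, comparison
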