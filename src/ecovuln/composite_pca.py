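"""Composite EVI: correlation-matrix PCA, component retention, and
variance-ratio weighting.

The observation matrix (cells x 15 standardized indicators) is centered
and scaled to unit variance, the correlation matrix is
eigendecomposed, and the components whose cumulative variance share
first reaches the retention threshold (default 80 %) are kept.  Each
retained component i receives the weight

    r_i = b_i / sum_j b_j      (b = eigenvalue, sum over retained j),

and the composite index is the weighted sum of component scores,
min-max rescaled to [0, 1] for classification.  The rescaling step is
required because component scores are centered and can be negative,
while the classification scheme lives on [0, 1]; both the raw and the
rescaled surfaces are retained.

Conventions: no rotation; eigenvector signs are fixed by making the
largest-magnitude loading of each component positive, which makes
repeated fits on the same matrix bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_model import RasterLayer
from .errors import DegenerateLayerError, RankError, StructuralError
from .preprocess import ObservationMatrix

__all__ = [
    "PCAResult",
    "WeightVector",
    "pca_fit",
    "retain_components",
    "variance_weights",
    "composite_evi",
    "rescale_unit",
]


@dataclass
class WeightVector:
    """Nonnegative weights summing to one, with a provenance tag."""

    weights: np.ndarray
    provenance: str = "user"  # variance-ratio | enhanced | user
    names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise StructuralError("weights must be nonnegative")
        s = self.weights.sum()
        if abs(s - 1.0) > 1e-9:
            raise StructuralError(f"weights must sum to 1, got {s!r}")

    def __len__(self) -> int:
        return len(self.weights)


@dataclass
class PCAResult:
    """Eigendecomposition of the indicator correlation matrix."""

    eigenvalues: np.ndarray  # descending, length p
    loadings: np.ndarray  # (p indicators, p components), unit eigenvectors
    scores: np.ndarray  # (n cells, p components)
    names: list[str]

    @property
    def p(self) -> int:
        return len(self.eigenvalues)

    @property
    def variance_pct(self) -> np.ndarray:
        """Per-component share of total variance, percent (100 b_i / p)."""
        return 100.0 * self.eigenvalues / self.p

    @property
    def cumulative_pct(self) -> np.ndarray:
        return np.cumsum(self.variance_pct)

    def report(self) -> pd.DataFrame:
        """Eigenvalue / %-variance / cumulative-% table per component."""
        return pd.DataFrame(
            {
                "component": np.arange(1, self.p + 1),
                "total": self.eigenvalues,
                "pct_variance": self.variance_pct,
                "cumulative_pct": self.cumulative_pct,
            }
        )

    def loadings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.loadings,
            index=self.names,
            columns=[f"PC{i + 1}" for i in range(self.p)],
        )


def pca_fit(matrix: ObservationMatrix) -> PCAResult:
    """Correlation-matrix PCA of the observation matrix.

    Requires at least two indicators, more valid cells than indicators,
    and no constant column (zero variance breaks the correlation
    scaling).
    """
    X = matrix.table.to_numpy(dtype=float)
    n, p = X.shape
    if p < 2:
        raise RankError(f"need >= 2 indicators, got {p}")
    if n <= p:
        raise RankError(f"need more valid cells ({n}) than indicators ({p})")
    std = X.std(axis=0, ddof=1)
    const = np.flatnonzero(std == 0)
    if const.size:
        raise DegenerateLayerError(
            f"constant indicator column {matrix.names[const[0]]!r}; "
            "correlation PCA undefined"
        )
    Z = (X - X.mean(axis=0)) / std
    corr = (Z.T @ Z) / (n - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign: largest-magnitude loading positive per component
    flip = np.sign(evecs[np.argmax(np.abs(evecs), axis=0), np.arange(p)])
    flip[flip == 0] = 1.0
    evecs = evecs * flip
    scores = Z @ evecs
    return PCAResult(evals, evecs, scores, list(matrix.names))


def retain_components(
    variance_pct: Sequence[float] | PCAResult, threshold: float = 0.80
) -> tuple[int, float]:
    """Smallest component count whose cumulative variance share reaches
    the threshold.

    Accepts either a fitted :class:`PCAResult` or a plain sequence of
    per-component variance percentages (e.g. a published table column).
    Returns ``(q, cumulative_pct)``.
    """
    if not (0.0 < threshold <= 1.0):
        raise StructuralError(f"threshold must be in (0, 1], got {threshold}")
    if isinstance(variance_pct, PCAResult):
        pct = variance_pct.variance_pct
    else:
        pct = np.asarray(variance_pct, dtype=float)
    cum = np.cumsum(pct)
    target = 100.0 * threshold
    hits = np.flatnonzero(cum >= target - 1e-9)
    q = int(hits[0]) + 1 if hits.size else len(pct)
    return q, float(cum[q - 1])


def variance_weights(eigenvalues: Sequence[float]) -> WeightVector:
    """Variance-ratio weights r_i = b_i / sum(b) over retained eigenvalues."""
    b = np.asarray(eigenvalues, dtype=float)
    if b.size < 1:
        raise StructuralError("need at least one eigenvalue")
    if np.any(b <= 0):
        raise StructuralError("retained eigenvalues must be positive")
    w = b / b.sum()
    w[-1] = 1.0 - w[:-1].sum()  # exact unit sum
    return WeightVector(w, provenance="variance-ratio")


def rescale_unit(vector: np.ndarray, name: str = "") -> np.ndarray:
    """Min-max rescale a vector to [0, 1]; constant input is an error."""
    vector = np.asarray(vector, dtype=float)
    lo, hi = np.nanmin(vector), np.nanmax(vector)
    if not np.isfinite(lo) or hi == lo:
        raise DegenerateLayerError(
            f"{name or 'surface'}: constant values cannot be min-max rescaled"
        )
    return (vector - lo) / (hi - lo)


def orientation_sign(raw: np.ndarray, matrix: ObservationMatrix) -> float:
    """±1 sign aligning a composite score with mean indicator level."""
    if np.std(raw) == 0:
        return 1.0  # constant score: orientation moot (rescale rejects it)
    mean_ind = matrix.table.to_numpy(dtype=float).mean(axis=1)
    r = np.corrcoef(raw, mean_ind)[0, 1]
    return -1.0 if np.isfinite(r) and r < 0 else 1.0


def orient_to_indicators(raw: np.ndarray, matrix: ObservationMatrix) -> np.ndarray:
    """Fix the sign of a composite score so higher means more vulnerable.

    Eigenvector signs are arbitrary, so a weighted component score could
    come out pointing either way.  The convention here: the index must
    correlate nonnegatively with the cell-wise mean of the standardized
    indicators (which, under direct polarity, rises with vulnerability);
    if it does not, the score is negated.  Deterministic and orientation
    data come only from the fitted matrix itself.
    """
    return orientation_sign(raw, matrix) * raw


def composite_evi(
    result: PCAResult | np.ndarray,
    weights: WeightVector,
    matrix: ObservationMatrix,
    name: str = "evi_pca",
) -> tuple[RasterLayer, RasterLayer]:
    """Weighted sum of retained component scores, as raw and [0, 1] rasters.

    Returns ``(raw, rescaled)`` surfaces; classification applies to the
    rescaled one.  The raw score is sign-oriented via
    :func:`orient_to_indicators` before rescaling.
    """
    scores = result.scores if isinstance(result, PCAResult) else np.asarray(result)
    q = len(weights)
    if scores.shape[1] < q:
        raise StructuralError(
            f"{q} weights but only {scores.shape[1]} score components"
        )
    if scores.shape[0] != matrix.n_cells:
        raise StructuralError("scores do not match the observation matrix cells")
    raw = orient_to_indicators(scores[:, :q] @ weights.weights, matrix)
    scaled = rescale_unit(raw, name)
    return (
        matrix.to_raster(raw, f"{name}_raw"),
        matrix.to_raster(scaled, name),
    )
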