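"""Spatial autocorrelation and system-comparison statistics.

Global Moran's I measures whether similar EVI values cluster in space
(I near +1), are random (I near E[I] = -1/(N-1)), or alternate (I near
-1).  Getis-Ord Gi* flags local hot spots (clusters of high values) and
cold spots via per-cell z-scores, classed at the two-sided normal 90 /
95 / 99 % thresholds (1.645, 1.960, 2.576) without multiple-testing
correction, matching common GIS practice.  Pearson correlation and OLS
regression compare the two index systems and their components.

Spatial weights are grid-contiguity based (rook = edge neighbors,
queen = edge + corner), restricted to the valid mask, optionally
row-standardized.  Gi* always uses binary contiguity plus a self-weight
of one (the "star" variant), whatever the row-standardize flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_model import RasterLayer
from .errors import DegenerateLayerError, RankError, StructuralError

__all__ = [
    "SpatialWeights",
    "build_weights",
    "MoranResult",
    "morans_i",
    "HotspotSurface",
    "getis_ord_gstar",
    "pearson_matrix",
    "LinearFit",
    "linear_fit",
]

_ROOK_OFFSETS = ((-1, 0), (1, 0), (0, -1), (0, 1))
_QUEEN_OFFSETS = _ROOK_OFFSETS + ((-1, -1), (-1, 1), (1, -1), (1, 1))

Z_THRESHOLDS = (1.645, 1.960, 2.576)  # 90 / 95 / 99 %, two-sided


@dataclass
class SpatialWeights:
    """Sparse contiguity weights over the valid cells of a grid."""

    mask: np.ndarray  # boolean grid mask
    cells: np.ndarray  # (N, 2) (row, col) of valid cells, row-major order
    adjacency: sp.csr_matrix  # binary, symmetric, zero diagonal
    w: sp.csr_matrix  # the weights actually used (maybe row-standardized)
    scheme: str
    row_standardized: bool

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    def neighbor_counts(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(int)


def build_weights(
    mask: np.ndarray, scheme: str = "queen", row_standardize: bool = True
) -> SpatialWeights:
    """Grid-contiguity weights restricted to a validity mask.

    Isolated cells (no neighbor inside the mask) keep zero rows; the
    statistics exclude them.  A mask where every cell is isolated is an
    error.
    """
    if scheme not in ("rook", "queen"):
        raise StructuralError(f"unknown contiguity scheme {scheme!r}")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise StructuralError("empty mask")
    nrows, ncols = mask.shape
    index = -np.ones(mask.shape, dtype=int)
    cells = np.argwhere(mask)
    index[mask] = np.arange(len(cells))

    offsets = _ROOK_OFFSETS if scheme == "rook" else _QUEEN_OFFSETS
    rows, cols = [], []
    r, c = cells[:, 0], cells[:, 1]
    for dr, dc in offsets:
        rr, cc = r + dr, c + dc
        ok = (rr >= 0) & (rr < nrows) & (cc >= 0) & (cc < ncols)
        ok[ok] &= mask[rr[ok], cc[ok]]
        rows.append(index[r[ok], c[ok]])
        cols.append(index[rr[ok], cc[ok]])
    i = np.concatenate(rows)
    j = np.concatenate(cols)
    n = len(cells)
    adj = sp.csr_matrix((np.ones(len(i)), (i, j)), shape=(n, n))
    if adj.nnz == 0:
        raise StructuralError("all cells are isolated; no contiguity structure")

    if row_standardize:
        deg = np.asarray(adj.sum(axis=1)).ravel()
        inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
        w = sp.diags(inv) @ adj
    else:
        w = adj.copy()
    return SpatialWeights(mask, cells, adj, w.tocsr(), scheme, row_standardize)


@dataclass
class MoranResult:
    I: float
    expected: float
    z_norm: float
    p_norm: float
    n: int
    perm_mean: float | None = None
    perm_p: float | None = None


def _valid_vector(surface: RasterLayer, weights: SpatialWeights) -> np.ndarray:
    if not np.array_equal(surface.valid_mask, weights.mask):
        raise StructuralError("surface validity mask does not match the weights")
    x = surface.values[weights.mask]
    if np.unique(x).size < 2:
        raise DegenerateLayerError(
            f"surface {surface.name!r} is constant; autocorrelation undefined"
        )
    return x


def morans_i(
    surface: RasterLayer,
    weights: SpatialWeights,
    permutations: int = 0,
    seed: int | None = None,
) -> MoranResult:
    """Global Moran's I with normality z-score and optional permutation test.

    I = (N / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2.
    """
    x = _valid_vector(surface, weights)
    W = weights.w
    n = len(x)
    z = x - x.mean()
    s0 = W.sum()
    num = float(z @ (W @ z))
    den = float(z @ z)
    I = (n / s0) * num / den

    e_i = -1.0 / (n - 1)
    # normality variance (standard closed form)
    Wt = W.T.tocsr()
    s1 = 0.5 * float(((W + Wt).power(2)).sum())
    row = np.asarray(W.sum(axis=1)).ravel()
    col = np.asarray(W.sum(axis=0)).ravel()
    s2 = float(((row + col) ** 2).sum())
    var = (n**2 * s1 - n * s2 + 3 * s0**2) / (s0**2 * (n**2 - 1)) - e_i**2
    z_norm = (I - e_i) / np.sqrt(var)
    from scipy.stats import norm

    p_norm = 2 * norm.sf(abs(z_norm))

    perm_mean = perm_p = None
    if permutations > 0:
        rng = np.random.default_rng(seed)
        sims = np.empty(permutations)
        for k in range(permutations):
            zp = rng.permutation(z)
            sims[k] = (n / s0) * float(zp @ (W @ zp)) / den
        perm_mean = float(sims.mean())
        extreme = np.count_nonzero(np.abs(sims - e_i) >= abs(I - e_i))
        perm_p = (extreme + 1) / (permutations + 1)
    return MoranResult(float(I), e_i, float(z_norm), float(p_norm), n, perm_mean, perm_p)


@dataclass
class HotspotSurface:
    """Per-cell Gi* z-scores and signed confidence classes.

    ``confidence`` holds 0 (not significant) or ±90/±95/±99, positive
    for hot spots (high-value clusters), negative for cold spots.
    """

    grid_z: RasterLayer
    confidence: np.ndarray  # int grid, 0 outside the mask too

    def class_counts(self) -> dict[int, int]:
        m = np.isfinite(self.grid_z.values)
        vals, counts = np.unique(self.confidence[m], return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


def _confidence_class(z: np.ndarray) -> np.ndarray:
    a = np.abs(z)
    cls = np.zeros(z.shape, dtype=int)
    cls[a >= Z_THRESHOLDS[0]] = 90
    cls[a >= Z_THRESHOLDS[1]] = 95
    cls[a >= Z_THRESHOLDS[2]] = 99
    return cls * np.sign(z).astype(int)


def getis_ord_gstar(surface: RasterLayer, weights: SpatialWeights) -> HotspotSurface:
    """Getis-Ord Gi* hot/cold-spot z-scores.

    Uses binary contiguity plus self (w_ii = 1).  For cell i,

        z_i = (sum_j w_ij x_j - xbar sum_j w_ij)
              / (S * sqrt[(N sum_j w_ij^2 - (sum_j w_ij)^2) / (N - 1)]),

    with S the global (population) standard deviation over the N valid
    cells.
    """
    x = _valid_vector(surface, weights)
    n = len(x)
    Wstar = (weights.adjacency + sp.eye(n, format="csr")).tocsr()
    wsum = np.asarray(Wstar.sum(axis=1)).ravel()  # binary: sum w = sum w^2
    wsq = wsum
    xbar = x.mean()
    S = np.sqrt((x**2).mean() - xbar**2)
    num = np.asarray(Wstar @ x).ravel() - xbar * wsum
    den = S * np.sqrt((n * wsq - wsum**2) / (n - 1))
    z = num / den

    zgrid = np.full(surface.grid.shape, np.nan)
    zgrid[weights.mask] = z
    conf = np.zeros(surface.grid.shape, dtype=int)
    conf[weights.mask] = _confidence_class(z)
    return HotspotSurface(
        RasterLayer(surface.grid, f"{surface.name}_gistar", zgrid, "z-score"), conf
    )


def pearson_matrix(columns: pd.DataFrame) -> pd.DataFrame:
    """Product-moment correlation matrix of named columns.

    Constant columns yield NaN rows/columns (flagged, never silently
    zero).
    """
    if len(columns) < 2:
        raise StructuralError("need at least 2 observations")
    X = columns.to_numpy(dtype=float)
    std = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.atleast_2d(corr)
    const = std == 0
    corr[const, :] = np.nan
    corr[:, const] = np.nan
    np.fill_diagonal(corr, np.where(const, np.nan, 1.0))
    return pd.DataFrame(corr, index=columns.columns, columns=columns.columns)


@dataclass
class LinearFit:
    """OLS fit summary: intercept-first coefficients and fit statistics."""

    coefficients: pd.Series  # index: ["intercept", predictors...]
    r2: float
    r2_adj: float
    names: list[str]

    @property
    def r(self) -> float:
        """Multiple R: positive square root of R²."""
        return float(np.sqrt(max(self.r2, 0.0)))


def linear_fit(y: np.ndarray, X: pd.DataFrame) -> LinearFit:
    """Ordinary least squares of y on the named predictor columns.

    Requires more observations than predictors and full column rank;
    rank deficiency is an error naming the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    names = list(X.columns)
    A = np.column_stack([np.ones(len(y)), X.to_numpy(dtype=float)])
    n, k = A.shape
    if n <= k - 1:
        raise RankError(f"need more observations ({n}) than predictors ({k - 1})")
    rank = np.linalg.matrix_rank(A)
    if rank < k:
        # identify columns whose removal restores full rank
        collinear = [
            names[j - 1]
            for j in range(1, k)
            if np.linalg.matrix_rank(np.delete(A, j, axis=1)) == rank
        ]
        raise RankError(f"rank-deficient design; collinear columns: {collinear}")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    dof = n - k
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / dof if dof > 0 else np.nan
    coeffs = pd.Series(beta, index=["intercept"] + names)
    return LinearFit(coeffs, r2, float(r2_adj), names)
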