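import numpy as np
import pytest

from ecovuln import (
    GridSpec,
    IdwParams,
    RasterLayer,
    SyntheticConfig,
    make_country,
)
from ecovuln.composite_pca import composite_evi, pca_fit, retain_components, variance_weights
from ecovuln.interpolation import idw_surface
from ecovuln.preprocess import build_matrix, minmax_normalize, resample_bilinear


def layer(values, cell_size=1000.0, name="layer") -> RasterLayer:
    """Small helper: wrap a 2-D array in a RasterLayer on a fresh grid."""
    values = np.asarray(values, dtype=float)
    grid = GridSpec(values.shape[0], values.shape[1], cell_size=cell_size)
    return RasterLayer(grid, name, values)


def standardized_stack(bundle):
    """Interpolate/resample/standardize a synthetic bundle's 15 indicators."""
    grid, mask = bundle.grid, bundle.mask
    layers = {}
    for name, st in bundle.stations.items():
        layers[name] = minmax_normalize(idw_surface(st, grid, IdwParams(), mask=mask))
    for name, lyr in bundle.rasters.items():
        if lyr.grid != grid:
            lyr = resample_bilinear(lyr, grid)
        lyr = lyr.with_values(np.where(mask, lyr.values, np.nan))
        layers[name] = minmax_normalize(lyr)
    return layers


def composite_from_bundle(bundle, threshold=0.80):
    """Bundle -> (matrix, PCAResult, q, weights, composite EVI layer)."""
    layers = standardized_stack(bundle)
    matrix = build_matrix(list(layers.values()), order=list(layers))
    pca = pca_fit(matrix)
    q, _ = retain_components(pca, threshold)
    w = variance_weights(pca.eigenvalues[:q])
    _, evi = composite_evi(pca, w, matrix)
    return matrix, pca, q, w, evi


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced synthetic country shared across tests (60x48 cells)."""
    return make_country(SyntheticConfig(seed=7, n_rows=60, n_cols=48))


@pytest.fixture(scope="session")
def small_stack(small_bundle):
    return standardized_stack(small_bundle)


@pytest.fixture(scope="session")
def small_matrix(small_bundle, small_stack):
    return build_matrix(list(small_stack.values()), order=list(small_stack))
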