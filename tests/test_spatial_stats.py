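"""Moran's I, Getis-Ord Gi*, Pearson correlation, and OLS."""

import numpy as np
import pandas as pd
import pytest

from ecovuln import (
    build_weights,
    getis_ord_gstar,
    linear_fit,
    morans_i,
    pearson_matrix,
)
from ecovuln.errors import DegenerateLayerError, RankError, StructuralError
from ecovuln.synthetic_data import gaussian_field
from ecovuln import GridSpec

from conftest import layer


def dense_weights(w):
    return np.asarray(w.w.todense())


def naive_morans_i(values, W):
    """O(N^2) reference evaluation of the Moran's I formula."""
    x = np.asarray(values, float)
    n = len(x)
    z = x - x.mean()
    s0 = W.sum()
    num = sum(W[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return (n / s0) * num / (z @ z)


def naive_gistar(values, A):
    """O(N^2) reference Gi* with binary adjacency + self."""
    x = np.asarray(values, float)
    n = len(x)
    xbar, S = x.mean(), np.sqrt((x**2).mean() - x.mean() ** 2)
    out = np.empty(n)
    for i in range(n):
        w = A[i].copy()
        w[i] = 1.0
        sw = w.sum()
        num = (w * x).sum() - xbar * sw
        den = S * np.sqrt((n * (w**2).sum() - sw**2) / (n - 1))
        out[i] = num / den
    return out


class TestWeights:
    def test_rook_and_queen_neighbor_counts(self):
        mask = np.ones((3, 3), bool)
        rook = build_weights(mask, "rook", False)
        queen = build_weights(mask, "queen", False)
        counts_r = rook.neighbor_counts().reshape(3, 3)
        counts_q = queen.neighbor_counts().reshape(3, 3)
        assert counts_r[1, 1] == 4 and counts_q[1, 1] == 8
        assert counts_r[0, 0] == 2 and counts_q[0, 0] == 3

    def test_row_standardized_rows_sum_to_one(self):
        w = build_weights(np.ones((4, 5), bool), "queen", True)
        sums = np.asarray(w.w.sum(axis=1)).ravel()
        assert np.allclose(sums, 1.0)

    def test_mask_restriction_and_errors(self):
        mask = np.zeros((3, 3), bool)
        mask[0, 0] = mask[2, 2] = True  # two isolated cells
        with pytest.raises(StructuralError, match="isolated"):
            build_weights(mask, "rook", True)
        with pytest.raises(StructuralError, match="empty"):
            build_weights(np.zeros((2, 2), bool), "rook", True)
        with pytest.raises(StructuralError, match="scheme"):
            build_weights(np.ones((2, 2), bool), "bishop", True)


class TestMoran:
    def test_expected_value_closed_form(self):
        lyr = layer(np.random.default_rng(0).random((5, 5)))
        w = build_weights(lyr.valid_mask, "queen", True)
        res = morans_i(lyr, w)
        assert res.expected == pytest.approx(-1.0 / 24)

    def test_checkerboard_is_minus_one(self):
        """Perfect alternation under rook contiguity: I = -1 exactly."""
        board = np.indices((4, 4)).sum(axis=0) % 2 * 2.0 - 1.0
        lyr = layer(board)
        w = build_weights(lyr.valid_mask, "rook", True)
        assert morans_i(lyr, w).I == pytest.approx(-1.0, abs=1e-12)

    @pytest.mark.parametrize("scheme,standardize", [("rook", True), ("queen", True),
                                                    ("rook", False), ("queen", False)])
    def test_naive_oracle_equivalence(self, scheme, standardize):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(8, 8))
        vals[rng.random((8, 8)) < 0.15] = np.nan
        lyr = layer(vals)
        w = build_weights(lyr.valid_mask, scheme, standardize)
        expected = naive_morans_i(vals[lyr.valid_mask], dense_weights(w))
        assert morans_i(lyr, w).I == pytest.approx(expected, abs=1e-10)

    def test_permutation_mean_matches_expectation(self):
        rng = np.random.default_rng(6)
        lyr = layer(rng.normal(size=(10, 10)))
        w = build_weights(lyr.valid_mask, "queen", True)
        res = morans_i(lyr, w, permutations=999, seed=1)
        assert res.perm_mean == pytest.approx(res.expected, abs=0.02)

    def test_smooth_vs_noise_magnitudes(self):
        grid = GridSpec(60, 60)
        w = build_weights(np.ones((60, 60), bool), "queen", True)
        smooth = gaussian_field(grid, 10.0, seed=2)
        noise = gaussian_field(grid, 0.0, seed=2)
        assert morans_i(smooth, w).I > 0.9
        assert abs(morans_i(noise, w).I) < 0.05

    def test_constant_surface_rejected(self):
        lyr = layer(np.ones((3, 3)))
        w = build_weights(lyr.valid_mask, "queen", True)
        with pytest.raises(DegenerateLayerError):
            morans_i(lyr, w)


class TestGiStar:
    def test_naive_oracle_equivalence(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(8, 8))
        vals[rng.random((8, 8)) < 0.1] = np.nan
        lyr = layer(vals)
        w = build_weights(lyr.valid_mask, "queen", True)
        hs = getis_ord_gstar(lyr, w)
        A = np.asarray(w.adjacency.todense())
        expected = naive_gistar(vals[lyr.valid_mask], A)
        assert np.allclose(hs.grid_z.values[lyr.valid_mask], expected, atol=1e-10)

    def test_single_spike_drives_the_hot_spot(self):
        """The maximal z sits in the spike's self-inclusive neighborhood
        and dominates every cell whose neighborhood excludes the spike."""
        vals = np.zeros((5, 5))
        vals[2, 2] = 10.0
        lyr = layer(vals + np.random.default_rng(8).normal(0, 0.01, (5, 5)))
        w = build_weights(lyr.valid_mask, "queen", True)
        z = getis_ord_gstar(lyr, w).grid_z.values
        r, c = np.unravel_index(np.nanargmax(z), (5, 5))
        assert max(abs(r - 2), abs(c - 2)) <= 1
        rr, cc = np.meshgrid(np.arange(5), np.arange(5), indexing="ij")
        far = np.maximum(np.abs(rr - 2), np.abs(cc - 2)) > 1
        assert z[2, 2] > z[far].max()

    def test_zscores_center_near_zero(self):
        rng = np.random.default_rng(9)
        lyr = layer(rng.normal(size=(20, 20)))
        w = build_weights(lyr.valid_mask, "queen", True)
        z = getis_ord_gstar(lyr, w).grid_z.values
        assert abs(np.nanmean(z)) < 0.1

    def test_confidence_classes_follow_thresholds(self):
        from ecovuln.spatial_stats import _confidence_class

        z = np.array([0.0, 1.7, -2.0, 3.0, -1.0])
        assert _confidence_class(z).tolist() == [0, 90, -95, 99, 0]

    def test_constant_surface_rejected(self):
        lyr = layer(np.full((3, 3), 2.0))
        w = build_weights(lyr.valid_mask, "queen", True)
        with pytest.raises(DegenerateLayerError):
            getis_ord_gstar(lyr, w)


class TestPearson:
    def test_exact_relationships(self):
        x = np.arange(8.0)
        df = pd.DataFrame({"x": x, "lin": 2 * x + 3, "neg": -x,
                           "d1": np.tile([1.0, 1.0, -1.0, -1.0], 2),
                           "d2": np.tile([1.0, -1.0, 1.0, -1.0], 2)})
        corr = pearson_matrix(df)
        assert corr.loc["x", "lin"] == pytest.approx(1.0)
        assert corr.loc["x", "neg"] == pytest.approx(-1.0)
        assert abs(corr.loc["d1", "d2"]) < 1e-12  # orthogonal ±1 designs
        assert np.allclose(corr.to_numpy(), corr.to_numpy().T)

    def test_matches_scipy_oracle(self):
        from scipy.stats import pearsonr

        rng = np.random.default_rng(10)
        df = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        corr = pearson_matrix(df)
        for i in "abc":
            for j in "abc":
                assert corr.loc[i, j] == pytest.approx(
                    pearsonr(df[i], df[j]).statistic, abs=1e-12
                )

    def test_constant_column_flagged_not_zero(self):
        df = pd.DataFrame({"a": np.arange(5.0), "flat": np.ones(5)})
        corr = pearson_matrix(df)
        assert np.isnan(corr.loc["flat", "a"])
        assert np.isnan(corr.loc["flat", "flat"])


class TestLinearFit:
    def test_exact_and_orthogonal(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["u", "v"])
        y = 1.5 * X.u - 2.0 * X.v + 4.0
        fit = linear_fit(y.to_numpy(), X)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.coefficients["u"] == pytest.approx(1.5)
        # a centered response orthogonal to the predictors
        ortho = pd.DataFrame({"d": np.tile([1.0, -1.0], 10)})
        y2 = np.tile([1.0, 1.0, -1.0, -1.0], 5)
        assert linear_fit(y2, ortho).r2 == pytest.approx(0.0, abs=1e-12)

    def test_r2_brute_force_and_statsmodels_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        y = X.a - 0.5 * X.b + rng.normal(0, 0.3, 50)
        fit = linear_fit(y.to_numpy(), X)
        # independent residual computation
        A = np.column_stack([np.ones(50), X])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        sse = float(((y - A @ beta) ** 2).sum())
        sst = float(((y - y.mean()) ** 2).sum())
        assert fit.r2 == pytest.approx(1 - sse / sst, abs=1e-10)
        res = sm.OLS(y, sm.add_constant(X)).fit()
        assert fit.r2 == pytest.approx(res.rsquared, abs=1e-10)
        assert fit.r2_adj == pytest.approx(res.rsquared_adj, abs=1e-10)
        assert fit.r == pytest.approx(np.sqrt(res.rsquared), abs=1e-10)

    def test_rank_deficiency_names_columns(self):
        X = pd.DataFrame({"a": np.arange(10.0), "b": 2 * np.arange(10.0)})
        with pytest.raises(RankError, match="collinear"):
            linear_fit(np.random.default_rng(13).normal(size=10), X)
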