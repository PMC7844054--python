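"""Best-subsets regression, clamp-and-normalize reweighting, enhanced EVI."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from ecovuln import best_subsets, enhanced_evi, linear_fit, reweight
from ecovuln import reference
from ecovuln.additive_index import additive_evi, equal_weights
from ecovuln.composite_pca import WeightVector, pca_fit, rescale_unit
from ecovuln.errors import RankError, StructuralError

from conftest import layer


class TestBestSubsets:
    def test_exact_recovery(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(100, 4)), columns=["p1", "p2", "p3", "p4"])
        y = 2.0 * X.p1 - 1.0 * X.p3 + 0.5
        res = best_subsets(y.to_numpy(), X)
        assert res.subset == ("p1", "p3")
        assert res.fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_exhaustive_oracle_equivalence(self):
        """The winner's criterion equals the max over an independent
        re-enumeration (5 predictors, 200 rows)."""
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(200, 5)), columns=list("abcde"))
        y = X.a + 0.3 * X.c + rng.normal(0, 0.5, 200)
        res = best_subsets(y.to_numpy(), X, criterion="adjr2")

        best_val, best_sub = -np.inf, None
        n = len(y)
        sst = float(((y - y.mean()) ** 2).sum())
        for size in range(1, 6):
            for combo in combinations(list("abcde"), size):
                A = np.column_stack([np.ones(n), X[list(combo)]])
                beta = np.linalg.solve(A.T @ A, A.T @ y)
                sse = float(((y - A @ beta) ** 2).sum())
                adj = 1 - (sse / sst) * (n - 1) / (n - size - 1)
                if adj > best_val:
                    best_val, best_sub = adj, combo
        assert res.subset == best_sub
        assert res.fit.r2_adj == pytest.approx(best_val, abs=1e-10)

    def test_single_predictor_equals_simple_ols(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"x": rng.normal(size=50)})
        y = 3.0 * X.x + rng.normal(0, 0.1, 50)
        res = best_subsets(y.to_numpy(), X)
        direct = linear_fit(y.to_numpy(), X)
        assert np.allclose(res.fit.coefficients, direct.coefficients)

    def test_deterministic_and_tie_break_toward_smaller(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        X["dup"] = X["a"]  # duplicate column: bigger subsets add nothing
        y = X.a * 2.0
        res = best_subsets(y.to_numpy(), X[["a", "dup", "b"]])
        assert res.subset == ("a",)  # perfect fit; the smallest, earliest subset
        res2 = best_subsets(y.to_numpy(), X[["a", "dup", "b"]])
        assert res.subset == res2.subset
        assert res.ranking.equals(res2.ranking)

    def test_rank_deficient_subsets_skipped(self):
        X = pd.DataFrame({"a": np.ones(20), "b": np.random.default_rng(4).normal(size=20)})
        y = X.b.to_numpy() * 2
        res = best_subsets(y, X)  # subsets containing only "a" are degenerate
        assert res.subset == ("b",)
        assert (res.ranking.note.str.contains("skipped")).any()

    def test_information_criteria_selectable(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(80, 3)), columns=list("abc"))
        y = X.a + rng.normal(0, 0.2, 80)
        for crit in ("aic", "bic"):
            res = best_subsets(y.to_numpy(), X, criterion=crit)
            assert "a" in res.subset


class TestReweight:
    def test_normalization_and_clamping(self):
        assert np.allclose(reweight([2.0, 1.0, 1.0]).weights, [0.5, 0.25, 0.25])
        assert np.allclose(reweight([3.0, -1.0]).weights, [1.0, 0.0])

    def test_excluded_components_get_zero(self):
        w = reweight([2.0, 2.0], component_names=["e", "s", "a"], selected=["e", "a"])
        assert np.allclose(w.weights, [0.5, 0.0, 0.5])
        assert w.provenance == "enhanced"

    def test_idempotent(self):
        w = reweight([0.3, 0.5, 0.2])
        again = reweight(w.weights)
        assert np.allclose(w.weights, again.weights, atol=1e-15)

    def test_all_nonpositive_rejected(self):
        with pytest.raises(StructuralError, match="nonpositive"):
            reweight([-1.0, 0.0])

    def test_published_enhanced_rows_are_valid_weights(self):
        for row in (reference.COMPOSITE_WEIGHTS_ENHANCED,
                    reference.ADDITIVE_WEIGHTS_ENHANCED):
            w = WeightVector(np.asarray(row), provenance="enhanced")
            assert w.weights.sum() == pytest.approx(1.0, abs=1e-9)


class TestEnhancedEvi:
    def test_identical_weights_give_zero_comparison(self, small_matrix):
        res = pca_fit(small_matrix)
        from ecovuln.composite_pca import composite_evi, variance_weights

        w = variance_weights(res.eigenvalues[:4])
        _, observed = composite_evi(res, w, small_matrix)
        _, comparison = enhanced_evi(
            "pca", w, matrix=small_matrix, scores=res.scores, observed=observed
        )
        assert (comparison.dif_km2 == 0).all()
        assert (comparison.qualification == "Stable").all()

    def test_concentrated_weight_equals_single_component(self, small_matrix):
        res = pca_fit(small_matrix)
        w = WeightVector([1.0, 0.0, 0.0], provenance="enhanced")
        surface, _ = enhanced_evi("pca", w, matrix=small_matrix, scores=res.scores)
        m = surface.valid_mask
        expected = rescale_unit(res.scores[:, 0])
        got = surface.values[m]
        assert np.allclose(got, expected, atol=1e-10) or np.allclose(
            got, 1 - expected, atol=1e-10
        )

    def test_additive_shift_toward_adaptation(self, small_stack, small_bundle):
        """Published enhanced weights (0.01, 0.19, 0.80) pull the EVI
        toward the adaptation layer's spatial pattern."""
        from ecovuln.additive_index import component_index

        groups = small_bundle.groups
        comps = [
            component_index(small_stack, [n for n in small_stack if groups[n] == c], c)
            for c in ("exposure", "sensitivity", "adaptation")
        ]
        observed = additive_evi(*comps, weights=equal_weights())
        enhanced, comparison = enhanced_evi(
            "additive",
            WeightVector(np.asarray(reference.ADDITIVE_WEIGHTS_ENHANCED),
                         provenance="enhanced"),
            components=comps,
            observed=observed,
        )
        m = observed.valid_mask
        adap = comps[2].values[m]
        rho_obs = spearmanr(observed.values[m], adap).statistic
        rho_enh = spearmanr(enhanced.values[m], adap).statistic
        assert rho_enh > rho_obs
        assert comparison is not None

    def test_self_calibration_recovers_observed_weights(self, small_matrix):
        """Regressing the composite EVI on its own retained components is
        exact, so best-subsets + reweight reproduces the observed
        variance-ratio weights (the enhancement default is idempotent)."""
        from ecovuln.composite_pca import composite_evi, retain_components, variance_weights

        from ecovuln.composite_pca import orientation_sign

        res = pca_fit(small_matrix)
        q, _ = retain_components(res, 0.80)
        w = variance_weights(res.eigenvalues[:q])
        _, evi = composite_evi(res, w, small_matrix)
        y = evi.values[evi.valid_mask]
        sign = orientation_sign(res.scores[:, :q] @ w.weights, small_matrix)
        preds = pd.DataFrame({f"PC{i+1}": sign * res.scores[:, i] for i in range(q)})
        bs = best_subsets(y, preds)
        assert bs.fit.r2 == pytest.approx(1.0, abs=1e-9)
        got = reweight(bs.fit.coefficients, component_names=list(preds.columns),
                       selected=list(bs.subset))
        assert np.allclose(got.weights, w.weights, atol=1e-6)

    def test_unknown_system(self):
        with pytest.raises(StructuralError):
            enhanced_evi("fuzzy", WeightVector([1.0]))
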