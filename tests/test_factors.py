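"""EFA building blocks against closed-form and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dogaging.config import BEHAVIOR_ITEMS, default_config
from dogaging.factors import (
    bartlett_sphericity,
    correlation_matrix,
    cronbach_alpha,
    explained_variance,
    extract_paf,
    implied_correlation,
    kmo,
    regression_scores,
    retain_and_prune,
    varimax_criterion,
    varimax_rotate,
)


def _align(A, B):
    """Best column permutation/sign of B to match A."""
    k = A.shape[1]
    from itertools import permutations

    best, err = None, np.inf
    for perm in permutations(range(k)):
        for signs in np.ndindex(*(2,) * k):
            s = np.array([1 if b == 0 else -1 for b in signs])
            cand = B[:, list(perm)] * s
            e = np.abs(cand - A).max()
            if e < err:
                best, err = cand, e
    return best, err


class TestCorrelationMatrix:
    def test_hand_example_matches_textbook_formula(self):
        df = pd.DataFrame({"a": [1., 2, 4, 3], "b": [2., 1, 5, 3], "c": [9., 7, 2, 4]})
        R = correlation_matrix(df)
        for i in "abc":
            for j in "abc":
                x, y = df[i].to_numpy(), df[j].to_numpy()
                num = ((x - x.mean()) * (y - y.mean())).sum()
                den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
                assert R.loc[i, j] == pytest.approx(num / den, abs=1e-12)
        assert np.allclose(np.diag(R), 1.0)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(20000, 2)), columns=["a", "b"])
        assert abs(correlation_matrix(df).loc["a", "b"]) < 0.03

    def test_zero_variance_names_item(self):
        df = pd.DataFrame({"a": [1., 2, 3], "flat": [5., 5, 5]})
        with pytest.raises(ValueError, match="flat"):
            correlation_matrix(df)


class TestKMO:
    def test_two_items_always_half(self):
        for r in (0.1, 0.5, -0.8):
            R = np.array([[1.0, r], [r, 1.0]])
            overall, _ = kmo(R)
            assert overall == pytest.approx(0.5, abs=1e-12)

    def test_reference_pattern_exceeds_08(self, implied_R8):
        overall, _ = kmo(implied_R8)
        assert overall >= 0.8

    def test_matches_brute_force_partial_correlations(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5000, 4)) @ rng.normal(size=(4, 4))
        R = np.corrcoef(X, rowvar=False)
        # brute force: partial corr of (i, j) given rest via regression residuals
        p = 4
        partial = np.zeros((p, p))
        for i in range(p):
            for j in range(i + 1, p):
                rest = [k for k in range(p) if k not in (i, j)]
                Z = np.column_stack([np.ones(len(X)), X[:, rest]])
                ri = X[:, i] - Z @ np.linalg.lstsq(Z, X[:, i], rcond=None)[0]
                rj = X[:, j] - Z @ np.linalg.lstsq(Z, X[:, j], rcond=None)[0]
                partial[i, j] = partial[j, i] = np.corrcoef(ri, rj)[0, 1]
        r2 = (R**2).sum() - p
        a2 = (partial**2).sum()
        expected = r2 / (r2 + a2)
        overall, _ = kmo(R)
        assert overall == pytest.approx(expected, abs=1e-10)


class TestBartlett:
    def test_identity_gives_zero(self):
        chi2, df, p = bartlett_sphericity(np.eye(5), 100)
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_df_formula(self):
        _, df, _ = bartlett_sphericity(np.eye(8), 100)
        assert df == 28

    def test_direct_evaluation_3x3(self):
        R = np.array([[1, .5, .2], [.5, 1, .3], [.2, .3, 1.]])
        n = 50
        chi2, df, p = bartlett_sphericity(R, n)
        expected = -(n - 1 - (2 * 3 + 5) / 6) * np.log(np.linalg.det(R))
        assert chi2 == pytest.approx(expected, rel=1e-12)
        assert p == pytest.approx(stats.chi2.sf(expected, 3), rel=1e-12)


class TestPAF:
    def test_identity_gives_zero_loadings(self):
        L, _, h2, info = extract_paf(np.eye(6), 1)
        assert np.abs(L).max() < 1e-8

    def test_single_factor_construction_recovered(self):
        lam = np.full(6, 0.8)
        R = implied_correlation(lam)
        L, _, h2, info = extract_paf(R, 1, tol=1e-8, max_iter=1000)
        np.testing.assert_allclose(L.ravel(), lam, atol=1e-6)

    def test_reference_pattern_recovered_after_rotation(
        self, implied_R8, reference_loadings_8
    ):
        L, _, _, _ = extract_paf(implied_R8, 2)
        rotated = varimax_rotate(L)
        aligned, err = _align(reference_loadings_8, rotated)
        assert err < 0.02


class TestVarimax:
    def test_simple_structure_is_fixed_point(self):
        L = np.array([[0.9, 0.0], [0.85, 0.0], [0.0, 0.8], [0.0, 0.75]])
        rotated = varimax_rotate(L)
        aligned, err = _align(L, rotated)
        assert err < 1e-6

    def test_matches_exhaustive_angle_grid(self, reference_loadings_8):
        L, _, _, _ = extract_paf(implied_correlation(reference_loadings_8), 2)
        rotated = varimax_rotate(L)
        # grid oracle with Kaiser row normalization, 0.01-degree steps
        norms = np.sqrt((L**2).sum(axis=1))
        A = L / norms[:, None]
        best = -np.inf
        for deg in np.arange(0, 90, 0.01):
            t = np.deg2rad(deg)
            Rm = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
            crit = varimax_criterion(A @ Rm)
            best = max(best, crit)
        ours = varimax_criterion(rotated / norms[:, None])
        assert ours >= best - 1e-6

    def test_row_norms_preserved(self, reference_loadings_8):
        rotated = varimax_rotate(reference_loadings_8)
        np.testing.assert_allclose(
            (rotated**2).sum(axis=1), (reference_loadings_8**2).sum(axis=1),
            atol=1e-10,
        )


class TestCronbach:
    def test_perfectly_correlated_pair(self):
        x = np.arange(10.0)
        assert cronbach_alpha(pd.DataFrame({"a": x, "b": x})) == pytest.approx(1.0)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(20000, 3)), columns=list("abc"))
        assert abs(cronbach_alpha(df)) < 0.05

    def test_three_item_direct_formula(self):
        df = pd.DataFrame({"a": [1., 3, 2, 5], "b": [2., 4, 1, 5], "c": [3., 3, 2, 6]})
        p = 3
        expected = p / (p - 1) * (
            1 - df.var(ddof=1).sum() / df.sum(axis=1).var(ddof=1)
        )
        assert cronbach_alpha(df) == pytest.approx(expected, abs=1e-12)

    def test_factor_alpha_ordering_matches_reference(self, implied_R8):
        # population ordering: the six-item factor is more consistent than
        # the two-item factor
        rng = np.random.default_rng(3)
        X = rng.multivariate_normal(np.zeros(8), implied_R8, size=30000)
        df = pd.DataFrame(X)
        assert cronbach_alpha(df[[0, 1, 2, 3, 4, 5]]) > cronbach_alpha(df[[6, 7]])


class TestRegressionScores:
    def test_single_item_identity(self):
        z = np.array([[-1.0], [0.0], [1.0]])
        s = regression_scores(z, np.array([[1.0]]), np.array([[1.0]]))
        np.testing.assert_allclose(s, z)

    def test_scores_centered(self, small_clean):
        model = retain_and_prune(small_clean[list(BEHAVIOR_ITEMS)])
        assert np.abs(model.scores.mean(axis=0)).max() < 1e-10

    def test_explicit_matrix_arithmetic(self):
        rng = np.random.default_rng(4)
        Z = rng.normal(size=(50, 3))
        L = rng.uniform(0.3, 0.8, size=(3, 1))
        R = implied_correlation(rng.uniform(0.4, 0.7, 3))
        expected = Z @ np.linalg.inv(R) @ L
        np.testing.assert_allclose(regression_scores(Z, L, R), expected, atol=1e-12)


class TestExplainedVariance:
    @pytest.mark.parametrize("eigs,p,expected", [
        ((3.952, 1.314), 8, 65.83),
        ((2.601,), 5, 52.02),
    ])
    def test_reference_arithmetic(self, eigs, p, expected):
        _, cum = explained_variance(eigs, p)
        assert cum == pytest.approx(expected, abs=0.01)

    def test_full_eigenvalues_give_hundred(self):
        _, cum = explained_variance([2.0, 1.5, 0.5], 4)
        assert cum == pytest.approx(100.0)


class TestRetainAndPrune:
    def test_low_variance_item_pruned_two_factors_remain(self, small_clean):
        model = retain_and_prune(small_clean[list(BEHAVIOR_ITEMS)])
        assert model.dropped_items == ["soc_owner"]
        assert model.n_factors == 2
        assert len(model.items) == 8

    def test_single_strong_factor_nothing_pruned(self):
        rng = np.random.default_rng(5)
        R = implied_correlation(np.full(5, 0.8))
        X = rng.multivariate_normal(np.zeros(5), R, size=5000)
        model = retain_and_prune(pd.DataFrame(X, columns=list("abcde")))
        assert model.n_factors == 1 and model.dropped_items == []

    def test_reference_pattern_two_factors(self, implied_R8):
        eig = np.sort(np.linalg.eigvalsh(implied_R8))[::-1]
        assert (eig > 1).sum() == 2
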