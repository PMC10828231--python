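"""Breakpoint splits, assumption checks, interaction models, and contrasts."""

import numpy as np
import pandas as pd
import pytest

from dogaging.slopes import (
    fit_random_intercept_model,
    fit_slope_model,
    levene_test,
    pairwise_slope_contrasts,
    split_at_breakpoint,
)


def _dataset(rng, slopes, n_per=300, sd=0.5, age_lo=10, age_hi=20, breeds=None):
    frames = []
    for g, s in slopes.items():
        age = rng.uniform(age_lo, age_hi, n_per)
        y = 1.0 + s * age + rng.normal(0, sd, n_per)
        f = pd.DataFrame({"age_years": age, "trait": y, "grp": g})
        if breeds is not None:
            f["breed"] = rng.choice(breeds, n_per)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


class TestSplit:
    def test_boundary_goes_before(self):
        df = pd.DataFrame({"age_years": [9.9, 10.0, 10.1], "grp": ["a"] * 3})
        before, after = split_at_breakpoint(df, {"a": 10.0}, "grp")
        assert list(before["age_years"]) == [9.9, 10.0]
        assert list(after["age_years"]) == [10.1]

    def test_partition_conserves_rows(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "age_years": rng.uniform(1, 20, 500),
            "grp": rng.choice(["a", "b"], 500),
        })
        before, after = split_at_breakpoint(df, {"a": 8.0, "b": 12.0}, "grp")
        assert len(before) + len(after) == 500
        assert set(before.index).isdisjoint(after.index)

    def test_group_specific_breakpoints(self):
        df = pd.DataFrame({"age_years": [9.0, 9.0], "grp": ["giant", "toy"]})
        before, after = split_at_breakpoint(df, {"giant": 7.1, "toy": 10.7}, "grp")
        assert after["grp"].tolist() == ["giant"]
        assert before["grp"].tolist() == ["toy"]

    def test_missing_breakpoint_raises(self):
        df = pd.DataFrame({"age_years": [5.0], "grp": ["a"]})
        with pytest.raises(KeyError):
            split_at_breakpoint(df, {"b": 3.0}, "grp")


class TestLevene:
    def test_identical_groups(self):
        v = [1.0, 2, 3, 4] * 2
        g = ["a"] * 4 + ["b"] * 4
        w, p = levene_test(v, g)
        assert w == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_detects_variance_ratio(self):
        rng = np.random.default_rng(1)
        v = np.concatenate([rng.normal(0, 1, 200), rng.normal(0, 3, 200)])
        g = ["a"] * 200 + ["b"] * 200
        _, p = levene_test(v, g)
        assert p < 0.01

    def test_calibrated_under_null(self):
        rng = np.random.default_rng(2)
        rej = 0
        for _ in range(100):
            v = rng.normal(0, 1, 200)
            g = ["a"] * 100 + ["b"] * 100
            if levene_test(v, g)[1] < 0.05:
                rej += 1
        assert rej <= 12

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            levene_test([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestSlopeModel:
    def test_noise_free_slopes_recovered(self):
        rng = np.random.default_rng(3)
        df = _dataset(rng, {"a": -0.1, "b": -0.3}, sd=0.0)
        res = fit_slope_model(df, "trait", "grp")
        cons = pairwise_slope_contrasts(res)
        assert cons[0].slope_a == pytest.approx(-0.1, abs=1e-10)
        assert cons[0].slope_b == pytest.approx(-0.3, abs=1e-10)

    def test_robust_and_classical_share_point_estimates(self):
        rng = np.random.default_rng(4)
        df = _dataset(rng, {"a": -0.1, "b": -0.2})
        res_c = fit_slope_model(df, "trait", "grp", robust=False)
        res_r = fit_slope_model(df, "trait", "grp", robust=True)
        pd.testing.assert_series_equal(
            res_c.coef_table["coef"], res_r.coef_table["coef"]
        )
        assert res_r.cov_type == "robust-sandwich"

    def test_heteroscedastic_data_triggers_robust(self):
        rng = np.random.default_rng(5)
        frames = []
        for g, sd in (("a", 0.2), ("b", 2.0)):
            age = rng.uniform(10, 20, 400)
            frames.append(pd.DataFrame({
                "age_years": age, "trait": 1 - 0.1 * age + rng.normal(0, sd, 400),
                "grp": g,
            }))
        res = fit_slope_model(pd.concat(frames), "trait", "grp")
        assert res.cov_type == "robust-sandwich"
        assert res.levene_p < 0.05

    def test_interaction_type_one_error_near_alpha(self):
        rng = np.random.default_rng(6)
        rej = 0
        reps = 100
        for _ in range(reps):
            df = _dataset(rng, {"a": -0.2, "b": -0.2}, n_per=150)
            res = fit_slope_model(df, "trait", "grp")
            if res.interaction_p < 0.05:
                rej += 1
        assert 0.01 <= rej / reps <= 0.10


class TestContrasts:
    def test_two_groups_single_contrast_unadjusted(self):
        rng = np.random.default_rng(7)
        res = fit_slope_model(_dataset(rng, {"a": -0.1, "b": -0.3}), "trait", "grp")
        cons = pairwise_slope_contrasts(res)
        assert len(cons) == 1
        assert cons[0].p_adjusted == pytest.approx(cons[0].p_raw)

    def test_six_groups_bonferroni_arithmetic(self):
        rng = np.random.default_rng(8)
        slopes = {g: -0.1 - 0.02 * i for i, g in enumerate("abcdef")}
        res = fit_slope_model(_dataset(rng, slopes, n_per=100), "trait", "grp")
        cons = pairwise_slope_contrasts(res)
        assert len(cons) == 15
        for c in cons:
            assert c.p_adjusted == pytest.approx(min(1.0, 15 * c.p_raw))

    def test_bonferroni_order_preserving(self):
        rng = np.random.default_rng(9)
        res = fit_slope_model(
            _dataset(rng, {"a": -0.1, "b": -0.2, "c": -0.3}), "trait", "grp"
        )
        cons = pairwise_slope_contrasts(res)
        raw = [c.p_raw for c in cons]
        adj = [c.p_adjusted for c in cons]
        assert np.argsort(raw).tolist() == np.argsort(adj).tolist()

    def test_partial_eta2_matches_anova_decomposition(self):
        rng = np.random.default_rng(10)
        df = _dataset(rng, {"a": -0.1, "b": -0.4}, n_per=60)
        res = fit_slope_model(df, "trait", "grp", robust=False)
        cons = pairwise_slope_contrasts(res)[0]
        # oracle: SS decomposition of the 1-df slope-difference contrast
        fit = res.fit
        X = fit.model.exog
        c = np.zeros(X.shape[1])
        names = fit.model.exog_names
        c[names.index([n for n in names if ":age" in n][0])] = 1.0
        est = float(c @ fit.params)
        ss_contrast = est**2 / float(c @ np.linalg.inv(X.T @ X) @ c)
        ss_error = float(fit.ssr)
        expected = ss_contrast / (ss_contrast + ss_error)
        assert cons.effect_size == pytest.approx(expected, abs=1e-10)


class TestRandomIntercept:
    def test_zero_heterogeneity_matches_plain_model(self):
        rng = np.random.default_rng(11)
        df = _dataset(rng, {"a": -0.1, "b": -0.3}, n_per=400,
                      breeds=[f"b{i}" for i in range(10)])
        plain = fit_slope_model(df, "trait", "grp", robust=False)
        mixed = fit_random_intercept_model(df, "trait", "grp")
        assert mixed.random_intercept_var == pytest.approx(0.0, abs=0.02)
        a = plain.coef_table["coef"]["age"]
        b = mixed.coef_table["coef"]["age"]
        assert b == pytest.approx(a, abs=0.01)

    def test_variance_component_recovered(self):
        rng = np.random.default_rng(12)
        breeds = [f"b{i}" for i in range(50)]
        offsets = dict(zip(breeds, rng.normal(0, 0.5, 50)))
        frames = []
        for br in breeds:
            age = rng.uniform(10, 20, 40)
            y = 1 + offsets[br] - 0.2 * age + rng.normal(0, 0.4, 40)
            frames.append(pd.DataFrame({
                "age_years": age, "trait": y, "breed": br,
                "grp": rng.choice(["a", "b"], 40),
            }))
        df = pd.concat(frames, ignore_index=True)
        mixed = fit_random_intercept_model(df, "trait", "grp")
        realized = float(np.var(list(offsets.values())))
        assert mixed.random_intercept_var == pytest.approx(realized, rel=0.2)

    def test_same_interaction_verdict_as_fixed_model(self):
        rng = np.random.default_rng(13)
        df = _dataset(rng, {"short": -0.1, "medium": -0.1, "long": -0.25},
                      n_per=500, breeds=[f"b{i}" for i in range(12)])
        plain = fit_slope_model(df, "trait", "grp")
        mixed = fit_random_intercept_model(df, "trait", "grp")
        assert (plain.interaction_p < 0.05) == (mixed.interaction_p < 0.05)
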