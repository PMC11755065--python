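import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import logit

from pairforage.pairs import (
    SeparationError,
    aicc,
    aicc_rank,
    build_pair_table,
    collinearity_filter,
    fit_weighted_logistic,
    matching_permutation_test,
    ttest_paired,
    ttest_unpaired,
    weighted_logistic_loglik,
)


def metrics_frame(f_vals, m_vals, trait="x", year="2022"):
    rows = []
    for i, v in enumerate(f_vals):
        rows.append({"bird_id": f"F{i}", "sex": "F", "year": year, trait: v})
    for i, v in enumerate(m_vals):
        rows.append({"bird_id": f"M{i}", "sex": "M", "year": year, trait: v})
    return pd.DataFrame(rows)


class TestBuildPairTable:
    def test_cross_product_row_count(self):
        df = metrics_frame(range(19), range(19))
        t = build_pair_table(df, {f"F{i}": f"M{i}" for i in range(19)}, ["x"])
        assert len(t) == 361
        assert t["is_real"].sum() == 19

    def test_toy_absolute_differences(self):
        df = metrics_frame([10, 20], [12, 30])
        t = build_pair_table(df, {"F0": "M0", "F1": "M1"}, ["x"])
        assert sorted(t["x"]) == [2, 8, 10, 20]

    def test_equal_traits_give_zero_difference(self):
        df = metrics_frame([5.0], [5.0])
        df2 = metrics_frame([7.0], [7.0], year="2023")
        t = build_pair_table(pd.concat([df, df2]), {"F0": "M0"}, ["x"])
        assert (t["x"] == 0).all()

    def test_weights_balance_classes_and_leave_traits_untouched(self):
        df = metrics_frame(np.arange(5.0), np.arange(5.0) + 1)
        pairs = {f"F{i}": f"M{i}" for i in range(5)}
        t = build_pair_table(df, pairs, ["x"])
        real = t[t["is_real"] == 1]
        rand = t[t["is_real"] == 0]
        assert (real["weight"] == len(rand) / len(real)).all()
        assert (rand["weight"] == 1.0).all()
        t0 = build_pair_table(df, pairs, ["x"], weight_mode="none")
        np.testing.assert_allclose(t0["x"], t["x"])  # weights never alter |Δ| columns

    def test_standardization_zscores_after_differencing(self):
        df = metrics_frame([10, 20, 30], [12, 25, 31])
        t = build_pair_table(df, {f"F{i}": f"M{i}" for i in range(3)}, ["x"], standardize_set=["x"])
        assert t["x"].mean() == pytest.approx(0.0, abs=1e-12)
        assert t["x"].std(ddof=1) == pytest.approx(1.0)


class TestCollinearityFilter:
    def test_duplicated_column_keeps_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        df = pd.DataFrame({"mean_a": x, "copy_a": x})
        kept, rec = collinearity_filter(df)
        assert kept == ["mean_a"]
        assert rec[0][2] == pytest.approx(1.0)

    def test_independent_columns_all_retained(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(1000, 4)), columns=list("abcd"))
        kept, rec = collinearity_filter(df)
        assert kept == list("abcd") and rec == []

    def test_mean_preferred_over_max_at_high_correlation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=500)
        noisy = x + rng.normal(0, 0.3, 500)  # r ≈ 0.96
        df = pd.DataFrame({"max_dive_duration": noisy, "mean_dive_duration": x})
        kept, _ = collinearity_filter(df)
        assert kept == ["mean_dive_duration"]

    def test_constant_column_excluded_with_warning(self):
        df = pd.DataFrame({"a": np.arange(10.0), "b": np.ones(10)})
        with pytest.warns(UserWarning, match="constant"):
            kept, _ = collinearity_filter(df)
        assert kept == ["a"]


class TestWeightedLogistic:
    def test_intercept_only_equals_logit_of_weighted_prevalence(self):
        rng = np.random.default_rng(3)
        y = (rng.random(200) < 0.3).astype(float)
        w = rng.uniform(0.5, 3.0, 200)
        fit = fit_weighted_logistic(np.ones((200, 1)), y, w)
        assert fit.coef[0] == pytest.approx(logit(np.sum(w * y) / np.sum(w)), abs=1e-8)

    def test_balanced_toy_matches_grid_search(self):
        X = np.column_stack([np.ones(40), np.repeat([-1.0, 1.0], 20)])
        y = np.concatenate([np.repeat([0.0, 1.0], [15, 5]), np.repeat([0.0, 1.0], [5, 15])])
        fit = fit_weighted_logistic(X, y)
        grid = np.linspace(-3, 3, 60001)
        lls = [weighted_logistic_loglik([0.0, b], X, y, np.ones(40)) for b in grid]
        assert fit.coef[1] == pytest.approx(grid[int(np.argmax(lls))], abs=1e-4)

    def test_weight_rescaling_leaves_estimates_unchanged(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([np.ones(100), rng.normal(size=100)])
        y = (rng.random(100) < 1 / (1 + np.exp(-X[:, 1]))).astype(float)
        w = rng.uniform(0.5, 2.0, 100)
        a = fit_weighted_logistic(X, y, w)
        b = fit_weighted_logistic(X, y, 7.3 * w)
        np.testing.assert_allclose(a.coef, b.coef, atol=1e-9)

    def test_separation_detected(self):
        X = np.column_stack([np.ones(20), np.linspace(-1, 1, 20)])
        y = (X[:, 1] > 0).astype(float)
        with pytest.raises(SeparationError):
            fit_weighted_logistic(X, y)

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError, match="degenerate response"):
            fit_weighted_logistic(np.ones((10, 1)), np.ones(10))

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_nelder_mead_on_random_instances(self, seed):
        """IRLS estimates match an independent derivative-free maximizer."""
        rng = np.random.default_rng(seed)
        n = 150
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        beta = rng.normal(0, 0.8, 3)
        y = (rng.random(n) < 1 / (1 + np.exp(-X @ beta))).astype(float)
        w = rng.uniform(0.5, 3.0, n)
        fit = fit_weighted_logistic(X, y, w)
        res = minimize(lambda b: -weighted_logistic_loglik(b, X, y, w), np.zeros(3),
                       method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 5000})
        np.testing.assert_allclose(fit.coef, res.x, atol=1e-4)

    def test_agrees_with_statsmodels_glm(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(99)
        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = (rng.random(n) < 1 / (1 + np.exp(-0.5 * X[:, 1]))).astype(float)
        w = rng.uniform(0.5, 2.0, n)
        fit = fit_weighted_logistic(X, y, w)
        glm = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w).fit()
        np.testing.assert_allclose(fit.coef, glm.params, atol=1e-6)
        np.testing.assert_allclose(fit.se, glm.bse, atol=1e-5)


class TestAICc:
    def test_closed_form_example(self):
        assert aicc(-100.0, 3, 100) == pytest.approx(206.25)

    def test_identical_models_split_weight(self):
        from pairforage.pairs import FitResult

        f1 = FitResult("a", np.zeros(1), np.ones(1), -50.0, 1, 100)
        f2 = FitResult("b", np.zeros(1), np.ones(1), -50.0, 1, 100)
        ranked = aicc_rank([f1, f2])
        assert all(f.aicc_weight == pytest.approx(0.5) for f in ranked)

    def test_single_candidate_weight_one(self):
        from pairforage.pairs import FitResult

        (f,) = aicc_rank([FitResult("a", np.zeros(1), np.ones(1), -50.0, 1, 100)])
        assert f.aicc_weight == 1.0

    def test_differing_n_rejected(self):
        from pairforage.pairs import FitResult

        f1 = FitResult("a", np.zeros(1), np.ones(1), -50.0, 1, 100)
        f2 = FitResult("b", np.zeros(1), np.ones(1), -50.0, 1, 101)
        with pytest.raises(ValueError):
            aicc_rank([f1, f2])


def pair_table_for_perm(f_vals, m_vals, pairs, year="2022"):
    df = metrics_frame(f_vals, m_vals, year=year)
    return build_pair_table(df, pairs, ["x"])


class TestMatchingPermutation:
    def test_tiny_year_exhaustive_enumeration(self):
        t = pair_table_for_perm([0.0, 10.0], [1.0, 12.0], {"F0": "M0", "F1": "M1"})
        p, t_obs, null = matching_permutation_test(t, "x", seed=0)
        assert len(null) == 2  # exactly two matchings of 2F x 2M
        # observed matching (diffs 1,2) mean 1.5 vs grand mean 6 → T = -4.5;
        # the swapped matching gives +4.5, so both matchings tie in |T| and
        # the exhaustive two-sided p is exactly 1
        assert t_obs == pytest.approx(-4.5)
        assert sorted(null) == pytest.approx([-4.5, 4.5])
        assert p == pytest.approx(1.0)

    def test_extreme_observed_statistic_hits_lower_bound(self):
        rng = np.random.default_rng(5)
        n = 8
        f = rng.normal(0, 1, n)
        m = f + 20.0 + rng.normal(0, 0.01, n)  # real mates enormously different
        perm_pairs = {f"F{i}": f"M{(i + 1) % n}" for i in range(n)}  # mismatched: real pairs similar
        t = pair_table_for_perm(f, m, {f"F{i}": f"M{i}" for i in range(n)})
        p, t_obs, null = matching_permutation_test(t, "x", n_perm=199, seed=1, exhaustive=False)
        assert p >= 1.0 / 200.0

    def test_statistic_zero_mean_under_null_matchings(self):
        rng = np.random.default_rng(6)
        t = pair_table_for_perm(rng.normal(size=6), rng.normal(size=6),
                                {f"F{i}": f"M{i}" for i in range(6)})
        _, _, null = matching_permutation_test(t, "x", n_perm=500, seed=2, exhaustive=False)
        # mean of the null statistic is ~0 (mean over all matchings = grand mean)
        assert abs(np.mean(null)) < 3 * np.std(null) / np.sqrt(len(null))

    def test_too_few_real_pairs_rejected(self):
        t = pair_table_for_perm([0.0, 1.0], [1.0, 2.0], {"F0": "M0"})
        t = t[t["female_id"] == "F0"]
        with pytest.raises(ValueError):
            matching_permutation_test(t, "x")


class TestTTests:
    def test_identical_samples_t_zero_p_one(self):
        t, df, p = ttest_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0 and df == 4

    def test_hand_computed_pooled_t(self):
        a = [1.0, 2.0, 3.0]
        b = [2.0, 4.0, 6.0]
        # pooled s2 = (2*1 + 2*4)/4 = 2.5 → t = (2-4)/sqrt(2.5*2/3)
        expected = -2.0 / np.sqrt(2.5 * 2.0 / 3.0)
        t, df, p = ttest_unpaired(a, b)
        assert t == pytest.approx(expected, abs=1e-10)
        assert df == 4

    def test_paired_detects_constant_shift_with_noise(self):
        rng = np.random.default_rng(7)
        before = rng.normal(981, 65, 40)
        after = before - rng.normal(20, 5, 40)
        t, df, p = ttest_paired(before, after)
        assert df == 39 and t > 0 and p < 1e-6

    def test_zero_variance_difference_rejected(self):
        with pytest.raises(ValueError):
            ttest_paired([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])
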