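"""Linear driver models: OLS, AICc selection, variance shares, ANOVA/Tukey."""

import math

import numpy as np
import pandas as pd
import pytest

from traitmoments import (
    aic,
    aicc,
    all_subsets_selection,
    fit_ols,
    oneway_anova_tukey,
    variance_shares,
)
from traitmoments.errors import CollinearityError, OverparameterizedModelError


def _pred(rng, n, m, prefix="x"):
    return pd.DataFrame(
        rng.normal(size=(n, m)), columns=[f"{prefix}{i + 1}" for i in range(m)]
    )


class TestFitOls:
    def test_perfect_linear_fit(self):
        x = np.arange(10.0)
        fit = fit_ols(2 * x + 1, pd.DataFrame({"x": x}))
        assert fit.r2 == pytest.approx(1.0)
        assert fit.adj_r2 == pytest.approx(1.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-18 * fit.tss + 1e-20)
        assert fit.coef["x"] == pytest.approx(2.0)
        assert fit.coef["Intercept"] == pytest.approx(1.0)

    def test_intercept_only(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=20)
        fit = fit_ols(y, pd.DataFrame(index=range(20)), terms=[])
        assert fit.rss == pytest.approx(np.sum((y - y.mean()) ** 2))
        assert fit.r2 == pytest.approx(0.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(30)
        X = _pred(rng, 30, 3)
        y = rng.normal(size=30)
        fit = fit_ols(y, X)
        # independent oracle: solve (X'X) beta = X'y directly
        Xd = np.column_stack([np.ones(30), X.to_numpy()])
        beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        np.testing.assert_allclose(fit.coef.to_numpy(), beta, atol=1e-8)

    def test_matches_statsmodels_with_factor(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(31)
        n = 24
        pred = _pred(rng, n, 2)
        pred["grp"] = np.repeat(["a", "b", "c"], 8)
        y = rng.normal(size=n) + (pred["grp"] == "c") * 2
        fit = fit_ols(y.to_numpy(), pred, factor="grp")
        dummies = pd.get_dummies(pred["grp"], drop_first=True, dtype=float)
        X = sm.add_constant(pd.concat([pred[["x1", "x2"]], dummies], axis=1))
        ref = sm.OLS(y, X).fit()
        assert fit.r2 == pytest.approx(ref.rsquared)
        assert fit.adj_r2 == pytest.approx(ref.rsquared_adj)
        np.testing.assert_allclose(
            np.sort(fit.coef.to_numpy()), np.sort(ref.params.to_numpy()), atol=1e-10
        )

    def test_collinearity_names_aliased_term(self):
        rng = np.random.default_rng(3)
        X = _pred(rng, 15, 2)
        X["x3"] = X["x1"] * 2.0
        with pytest.raises(CollinearityError) as err:
            fit_ols(rng.normal(size=15), X)
        assert "x3" in err.value.aliased


class TestAicc:
    def _fit(self, n, k_terms, seed=5):
        rng = np.random.default_rng(seed)
        X = _pred(rng, n, k_terms)
        return fit_ols(rng.normal(size=n), X)

    def test_correction_term_value(self):
        fit = self._fit(100, 1)  # k = intercept + slope + variance = 3
        assert fit.k == 3
        assert aicc(fit) - aic(fit) == pytest.approx(2 * 3 * 4 / 96)

    def test_aicc_exceeds_aic(self):
        fit = self._fit(25, 3)
        assert aicc(fit) > aic(fit)

    def test_formula_oracle(self):
        fit = self._fit(40, 2)
        n, k = fit.n, fit.k
        expected = (
            n * math.log(fit.rss / n)
            + n * math.log(2 * math.pi)
            + n
            + 2 * k
            + 2 * k * (k + 1) / (n - k - 1)
        )
        assert aicc(fit) == pytest.approx(expected, abs=1e-10)

    def test_overparameterized_error(self):
        fit = self._fit(8, 5)  # k = 7, n - k - 1 = 0
        with pytest.raises(OverparameterizedModelError):
            aicc(fit)

    def test_ranking_invariant_to_response_shift(self):
        rng = np.random.default_rng(8)
        X = _pred(rng, 40, 4)
        y = 2 * X["x1"].to_numpy() + rng.normal(size=40)
        a = all_subsets_selection(y, X)
        b = all_subsets_selection(y + 100.0, X)
        assert a.candidates["terms"].tolist() == b.candidates["terms"].tolist()
        np.testing.assert_allclose(
            a.candidates["delta_aicc"], b.candidates["delta_aicc"], atol=1e-8
        )


class TestAllSubsets:
    def test_enumerates_all_subsets(self):
        rng = np.random.default_rng(10)
        X = _pred(rng, 200, 9)
        sel = all_subsets_selection(rng.normal(size=200), X)
        assert len(sel.candidates) == 512

    def test_factor_enters_as_block(self):
        rng = np.random.default_rng(11)
        pred = _pred(rng, 30, 2)
        pred["grp"] = np.tile(["a", "b", "c"], 10)
        sel = all_subsets_selection(
            rng.normal(size=30), pred, factor="grp"
        )
        assert len(sel.candidates) == 8  # 2^3 term subsets
        with_factor = sel.candidates["terms"].str.contains("grp")
        assert with_factor.sum() == 4

    def test_single_forced_term_reproduces_fit_ols(self):
        rng = np.random.default_rng(12)
        X = _pred(rng, 25, 1)
        y = 1.5 * X["x1"].to_numpy() + rng.normal(size=25)
        sel = all_subsets_selection(y, X, terms=["x1"])
        direct = fit_ols(y, X, terms=["x1"])
        assert sel.best_terms == ["x1"]
        row = sel.candidates[sel.candidates.terms == "x1"].iloc[0]
        assert row["rss"] == pytest.approx(direct.rss)
        assert sel.best.coef["x1"] == pytest.approx(direct.coef["x1"])

    def test_strong_signal_always_selected(self):
        rng = np.random.default_rng(13)
        hits = 0
        for _ in range(30):
            X = _pred(rng, 60, 8)
            y = 3.0 * X["x1"].to_numpy() + rng.normal(0, 0.5, 60)
            sel = all_subsets_selection(y, X)
            hits += "x1" in sel.best_terms
        assert hits == 30

    def test_pure_noise_supports_intercept_only(self):
        rng = np.random.default_rng(14)
        majority = 0
        for _ in range(40)    :
            X = _pred(rng, 60, 7)
            sel = all_subsets_selection(rng.normal(size=60), X)
            majority += (sel.supported["terms"] == "1").any()
        assert majority > 20

    def test_noise_predictor_usually_lowers_adj_r2(self):
        # adjusted R2 rises only when the noise term's partial F exceeds 1
        # (probability ~ 1/3), so the typical replicate sees a decrease;
        # the mean change is exactly zero by construction of the adjustment
        rng = np.random.default_rng(15)
        diffs = []
        for _ in range(500):
            X = _pred(rng, 30, 2)
            y = X["x1"].to_numpy() + rng.normal(size=30)
            small = fit_ols(y, X, terms=["x1"])
            big = fit_ols(y, X, terms=["x1", "x2"])
            diffs.append(big.adj_r2 - small.adj_r2)
        assert np.mean(np.array(diffs) < 0) > 0.55


class TestVarianceShares:
    def test_single_predictor_share_equals_r2(self):
        rng = np.random.default_rng(20)
        X = _pred(rng, 40, 1)
        y = 2 * X["x1"].to_numpy() + rng.normal(size=40)
        fit = fit_ols(y, X)
        shares = variance_shares(fit)
        assert shares.set_index("term").loc["x1", "pct_of_total"] == pytest.approx(
            100 * fit.r2
        )

    def test_orthogonal_design_shares_sum_to_100(self):
        rng = np.random.default_rng(21)
        raw = rng.normal(size=(50, 3))
        q, _ = np.linalg.qr(np.column_stack([np.ones(50), raw]))
        X = pd.DataFrame(q[:, 1:], columns=["x1", "x2", "x3"])  # centred, orthogonal
        y = q[:, 1] + 0.5 * q[:, 2] + rng.normal(0, 0.05, 50)
        fit = fit_ols(y, X)
        shares = variance_shares(fit)
        assert shares["pct_of_total"].sum() == pytest.approx(100.0, abs=1e-8)
        # sequential-SS oracle: for orthogonal terms, each SS equals the
        # drop in RSS when the term is added first
        base = fit_ols(y, X, terms=[])
        for term in ["x1", "x2", "x3"]:
            seq = base.rss - fit_ols(y, X, terms=[term]).rss
            got = shares.set_index("term").loc[term, "ss"]
            assert got == pytest.approx(seq, abs=1e-8)

    def test_balanced_factor_ss_equals_anova_between_ss(self):
        rng = np.random.default_rng(22)
        groups = np.repeat(["a", "b", "c"], 10)
        y = rng.normal(size=30) + (groups == "b") * 1.5
        pred = pd.DataFrame({"grp": groups})
        fit = fit_ols(y, pred, factor="grp")
        shares = variance_shares(fit)
        means = [y[groups == g].mean() for g in "abc"]
        between = 10 * sum((m - y.mean()) ** 2 for m in means)
        assert shares.set_index("term").loc["grp", "ss"] == pytest.approx(between)

    def test_matches_statsmodels_type2(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols as sm_ols

        rng = np.random.default_rng(23)
        df = _pred(rng, 40, 2)
        df["y"] = df.x1 + 0.3 * df.x2 + rng.normal(size=40)
        fit = fit_ols(df["y"].to_numpy(), df[["x1", "x2"]])
        shares = variance_shares(fit).set_index("term")
        table = sm.stats.anova_lm(sm_ols("y ~ x1 + x2", df).fit(), typ=2)
        for term in ("x1", "x2"):
            assert shares.loc[term, "ss"] == pytest.approx(
                table.loc[term, "sum_sq"], rel=1e-8
            )


class TestAnovaTukey:
    def test_two_groups_equal_pooled_t_test(self):
        from scipy import stats

        rng = np.random.default_rng(31)
        a, b = rng.normal(size=12), rng.normal(0.8, 1.0, size=15)
        res = oneway_anova_tukey(
            np.concatenate([a, b]), ["a"] * 12 + ["b"] * 15
        )
        t_p = stats.ttest_ind(a, b, equal_var=True).pvalue
        assert res.pairwise.iloc[0]["p_adj"] == pytest.approx(t_p, abs=1e-6)
        assert res.p_value == pytest.approx(t_p, abs=1e-6)

    def test_identical_groups_share_letter(self):
        vals = [2.0] * 12
        res = oneway_anova_tukey(vals, ["a", "b", "c"] * 4)
        assert res.f_statistic == 0.0
        assert set(res.letters.values()) == {"a"}

    def test_separated_groups_distinct_letters(self):
        rng = np.random.default_rng(33)
        vals = np.concatenate(
            [rng.normal(0, 0.1, 10), rng.normal(5, 0.1, 10), rng.normal(10, 0.1, 10)]
        )
        res = oneway_anova_tukey(vals, ["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        assert len(set(res.letters.values())) == 3
        assert (res.pairwise["p_adj"] < 0.05).all()

    def test_matches_scipy_tukey_hsd(self):
        from scipy.stats import tukey_hsd

        rng = np.random.default_rng(34)
        groups = [rng.normal(m, 1.0, 10) for m in (0.0, 0.5, 1.5)]
        res = oneway_anova_tukey(
            np.concatenate(groups), ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        )
        ref = tukey_hsd(*groups)
        got = res.pairwise.set_index(["group_a", "group_b"])["p_adj"]
        for (i, j), key in [((0, 1), ("a", "b")), ((0, 2), ("a", "c")), ((1, 2), ("b", "c"))]:
            assert got[key] == pytest.approx(ref.pvalue[i, j], abs=1e-8)

    def test_pairwise_p_matches_null_simulation(self):
        # simulate the studentized-range null for 3 groups of 10 and check
        # the adjusted p of an observed q against the empirical tail
        rng = np.random.default_rng(35)
        g, n = 3, 10
        draws = rng.normal(size=(20000, g, n))
        means = draws.mean(axis=2)
        mse = draws.var(axis=2, ddof=1).mean(axis=1)
        q_null = (means.max(axis=1) - means.min(axis=1)) / np.sqrt(mse / n)
        for q_obs in (2.0, 3.0, 4.0):
            from scipy import stats

            p_exact = stats.studentized_range.sf(q_obs, g, g * (n - 1))
            p_mc = (q_null >= q_obs).mean()
            se = math.sqrt(p_mc * (1 - p_mc) / len(q_null)) + 1e-4
            assert p_exact == pytest.approx(p_mc, abs=4 * se)

    def test_small_group_excluded_with_warning(self):
        vals = [1.0, 2.0, 1.5, 2.5, 9.9]
        grps = ["a", "a", "b", "b", "c"]
        with pytest.warns(UserWarning, match="excluding"):
            res = oneway_anova_tukey(vals, grps)
        assert res.excluded_groups == ["c"]

    def test_type1_error_calibrated(self):
        rng = np.random.default_rng(36)
        reps, hits = 2000, 0
        groups = np.repeat(list("abcdef"), 10)
        for _ in range(reps):
            res = oneway_anova_tukey(rng.normal(size=60), groups, tukey=False)
            hits += res.p_value < 0.05
        assert 0.035 < hits / reps < 0.065
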