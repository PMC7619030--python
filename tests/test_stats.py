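"""The interaction OLS and crossed random-intercepts REML machinery."""

import numpy as np
import pandas as pd
import pytest
import scipy.optimize
import statsmodels.api as sm

from lexmap.stats import (
    CrossedLMM,
    GroupInteractionOLS,
    fit_crossed_lmm,
    fit_lm_interaction,
    interaction_design,
    parse_mixed_formula,
)


def _crossed_data(seed, q1=20, q2=20, s1=1.0, s2=1.0, se=1.0, slope=0.5, full=True):
    """Fully crossed q1 x q2 layout with known variance components."""
    rng = np.random.default_rng(seed)
    i1 = np.repeat(np.arange(q1), q2)
    i2 = np.tile(np.arange(q2), q1)
    n = len(i1)
    x = rng.standard_normal(n)
    y = (
        1.0
        + slope * x
        + rng.normal(0, np.sqrt(s1), q1)[i1]
        + rng.normal(0, np.sqrt(s2), q2)[i2]
        + rng.normal(0, np.sqrt(se), n)
    )
    X = np.column_stack([np.ones(n), x])
    ids1 = np.array([f"a{i}" for i in i1])
    ids2 = np.array([f"b{j}" for j in i2])
    return y, X, x, ids1, ids2


class TestInteractionDesign:
    def test_single_group_degenerates_to_simple_regression(self, rng):
        x = rng.standard_normal(50)
        y = 2.0 + 3.0 * x + rng.normal(0, 0.1, 50)
        res = fit_lm_interaction(y, x)
        closed = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert res.params["x"] == pytest.approx(closed, rel=1e-10)

    def test_parameter_count_and_residual_df(self, rng):
        # 5 groups with the station counts of the five networks: 1083 rows,
        # 2*5 parameters, residual df 1073
        sizes = [175, 265, 241, 107, 295]
        groups = np.concatenate([[f"g{k}"] * n for k, n in enumerate(sizes)])
        x = rng.standard_normal(len(groups))
        y = rng.standard_normal(len(groups))
        res = fit_lm_interaction(y, x, groups)
        assert res.nobs == 1083
        assert len(res.params) == 10
        assert res.df_resid == 1073

    def test_exactly_linear_groups_have_zero_residual(self, rng):
        groups = np.repeat(["a", "b"], 30)
        x = rng.standard_normal(60)
        y = np.where(groups == "a", 1.0 + 2.0 * x, -0.5 + 0.3 * x)
        res = fit_lm_interaction(y, x, groups)
        assert float(res.resid @ res.resid) < 1e-10

    def test_sum_contrasts_sum_to_zero(self, rng):
        x = rng.standard_normal(30)
        groups = np.repeat(["a", "b", "c"], 10)
        X, info = interaction_design(x, groups, coding="sum")
        # each level's group-contrast row summed over levels is zero
        block = X[[0, 10, 20]][:, info.group_cols]
        np.testing.assert_allclose(block.sum(axis=0), 0.0, atol=1e-12)

    def test_constant_predictor_within_group_rejected(self):
        x = np.array([1.0, 1.0, 1.0, 0.0, 1.0, 2.0])
        groups = np.array(["a"] * 3 + ["b"] * 3)
        with pytest.raises(ValueError, match="constant"):
            GroupInteractionOLS(np.zeros(6), x, groups)


class TestOLSTermTests:
    def test_exactly_null_interaction_term(self, rng):
        # group b is an exact intercept-shifted copy of group a, so the
        # slope difference (the interaction coefficient) is exactly zero
        # while the residual variance stays finite
        x_half = rng.standard_normal(40)
        y_half = 1.0 + 2.0 * x_half + rng.normal(0, 0.5, 40)
        x = np.concatenate([x_half, x_half])
        y = np.concatenate([y_half, y_half - 1.0])
        groups = np.repeat(["a", "b"], 40)
        tt = fit_lm_interaction(y, x, groups).term_tests().set_index("term")
        assert tt.loc["x:group", "F"] == pytest.approx(0.0, abs=1e-12)
        assert tt.loc["x:group", "p"] == pytest.approx(1.0, abs=1e-12)

    def test_f_matches_statsmodels_single_df(self, rng):
        x = rng.standard_normal(100)
        groups = np.repeat(["a", "b"], 50)
        y = x + rng.standard_normal(100)
        res = fit_lm_interaction(y, x, groups)
        tt = res.term_tests().set_index("term")
        # single-df term: F equals t^2 of the corresponding coefficient
        assert tt.loc["x", "F"] == pytest.approx(res.tvalues["x"] ** 2, rel=1e-10)


class TestSimpleSlopesOLS:
    def test_single_group_slope_is_x_coefficient(self, rng):
        x = rng.standard_normal(40)
        y = 0.5 * x + rng.normal(0, 0.2, 40)
        res = fit_lm_interaction(y, x)
        slopes = res.simple_slopes()
        assert len(slopes) == 1
        assert slopes[0].slope == pytest.approx(res.params["x"], rel=1e-12)

    def test_coding_invariance(self, rng):
        x = rng.standard_normal(90)
        groups = np.repeat(["a", "b", "c"], 30)
        y = x * np.repeat([0.5, -0.2, 1.0], 30) + rng.normal(0, 0.3, 90)
        s_sum = {s.group: s for s in fit_lm_interaction(y, x, groups, coding="sum").simple_slopes()}
        s_trt = {s.group: s for s in fit_lm_interaction(y, x, groups, coding="treatment").simple_slopes()}
        for g in "abc":
            assert s_trt[g].slope == pytest.approx(s_sum[g].slope, abs=1e-10)
            assert s_trt[g].se == pytest.approx(s_sum[g].se, abs=1e-10)

    def test_level_relabeling_permutes_slopes(self, rng):
        x = rng.standard_normal(60)
        groups = np.repeat(["a", "b"], 30)
        y = x * np.repeat([1.0, -1.0], 30) + rng.normal(0, 0.3, 60)
        base = {s.group: s.slope for s in fit_lm_interaction(y, x, groups).simple_slopes()}
        relabeled = np.where(groups == "a", "zz", "aa")
        out = {s.group: s.slope for s in fit_lm_interaction(y, x, relabeled).simple_slopes()}
        assert out["zz"] == pytest.approx(base["a"], abs=1e-10)
        assert out["aa"] == pytest.approx(base["b"], abs=1e-10)

    def test_recovers_generating_slopes(self):
        rng = np.random.default_rng(777)
        gen = {"g0": 0.04, "g1": 0.03, "g2": 0.01, "g3": 0.05, "g4": 0.02}
        n = 500
        groups = np.repeat(list(gen), n)
        x = rng.standard_normal(len(groups))
        y = x * np.repeat(list(gen.values()), n) + rng.normal(0, 0.5, len(groups))
        slopes = fit_lm_interaction(y, x, groups).simple_slopes()
        for s in slopes:
            assert abs(s.slope - gen[s.group]) < 3 * s.se


class TestCrossedLMMFit:
    def test_zero_variance_data_reduces_to_ols(self):
        rng = np.random.default_rng(5)
        n = 400
        x = rng.standard_normal(n)
        y = 1.0 + 0.5 * x + rng.normal(0, 1.0, n)  # no random structure
        X = np.column_stack([np.ones(n), x])
        ids1 = np.array([f"a{i}" for i in rng.integers(0, 20, n)])
        ids2 = np.array([f"b{i}" for i in rng.integers(0, 20, n)])
        res = fit_crossed_lmm(y, X, ids1, ids2, exog_names=["Intercept", "x"])
        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(res.params.to_numpy(), ols.params, rtol=1e-4)
        if all(res.boundary.values()):
            np.testing.assert_allclose(res.params.to_numpy(), ols.params, rtol=1e-6)
            assert res.scale == pytest.approx(ols.scale, rel=1e-6)

    def test_matches_statsmodels_variance_components(self):
        y, X, x, ids1, ids2 = _crossed_data(42, q1=25, q2=20, s1=0.8, s2=1.5)
        res = CrossedLMM(y, X, ids1, ids2, ["Intercept", "x"]).fit()
        df = pd.DataFrame({"y": y, "x": x, "id1": ids1, "id2": ids2, "g": 1})
        md = sm.MixedLM.from_formula(
            "y ~ x",
            groups="g",
            vc_formula={"id1": "0 + C(id1)", "id2": "0 + C(id2)"},
            re_formula="0",
            data=df,
        )
        mres = md.fit(reml=True)
        np.testing.assert_allclose(res.params.to_numpy(), mres.params.iloc[:2], rtol=1e-5)
        assert res.sigma2_resid == pytest.approx(mres.scale, rel=1e-3)
        assert res.sigma2_id1 == pytest.approx(mres.vcomp[0], rel=2e-3)
        assert res.sigma2_id2 == pytest.approx(mres.vcomp[1], rel=2e-3)

    def test_optimum_beats_variance_ratio_grid(self):
        """The returned optimum is at least as good as a 50x50 grid search."""
        y, X, _, ids1, ids2 = _crossed_data(7, q1=12, q2=12)
        model = CrossedLMM(y, X, ids1, ids2)
        res = model.fit()
        grid = np.exp(np.linspace(-8, 4, 50))
        best_grid = min(
            model.criterion(g1, g2) for g1 in grid for g2 in grid
        )
        assert res.deviance <= best_grid + 1e-6

    def test_balanced_one_way_matches_anova_closed_form(self):
        """With one active factor, REML equals the ANOVA estimator:
        sigma_e^2 = MS_within, sigma_1^2 = (MS_between - MS_within) / m."""
        rng = np.random.default_rng(11)
        q, m = 15, 8
        i1 = np.repeat(np.arange(q), m)
        y = 2.0 + rng.normal(0, 1.2, q)[i1] + rng.normal(0, 0.7, q * m)
        X = np.ones((q * m, 1))
        model = CrossedLMM(
            y, X, [f"a{i}" for i in i1], [f"b{j}" for j in np.tile(np.arange(m), q)]
        )
        res = model.fit()
        assert res.boundary["id2"] and not res.boundary["id1"]
        sigma_e = res.sigma2_resid
        sigma_1 = res.sigma2_id1
        grand = y.reshape(q, m)
        msw = ((grand - grand.mean(axis=1, keepdims=True)) ** 2).sum() / (q * (m - 1))
        msb = m * ((grand.mean(axis=1) - grand.mean()) ** 2).sum() / (q - 1)
        assert sigma_e == pytest.approx(msw, rel=1e-8)
        assert sigma_1 == pytest.approx((msb - msw) / m, rel=1e-8)

    def test_variance_recovery_short(self):
        """Quick 20-replicate recovery check at (1, 1, 1) on a 40x40 design."""
        est = []
        for seed in range(20):
            y, X, _, ids1, ids2 = _crossed_data(100 + seed, q1=40, q2=40)
            r = CrossedLMM(y, X, ids1, ids2).fit(n_restarts=3)
            est.append([r.sigma2_id1, r.sigma2_id2, r.sigma2_resid])
        est = np.array(est)
        mean = est.mean(axis=0)
        mcse = est.std(axis=0, ddof=1) / np.sqrt(len(est))
        for k in range(3):
            assert abs(mean[k] - 1.0) < 3 * mcse[k]

    def test_identical_ids_in_row_rejected(self):
        X = np.ones((3, 1))
        with pytest.raises(ValueError, match="distinct"):
            CrossedLMM([1.0, 2.0, 3.0], X, ["a", "b", "a"], ["a", "c", "c"])

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(ValueError, match="rank"):
            CrossedLMM(
                np.arange(10.0), X,
                [f"a{i}" for i in range(10)], [f"b{i}" for i in range(10)],
            )


class TestLMMInference:
    def test_wald_chi2_equals_z_squared_for_single_coefficient(self):
        y, X, x, ids1, ids2 = _crossed_data(3, q1=15, q2=15)
        res = CrossedLMM(y, X, ids1, ids2, ["Intercept", "x"],
                         terms={"Intercept": [0], "x": [1]}).fit()
        tt = res.term_tests("wald").set_index("term")
        assert tt.loc["x", "chi2"] == pytest.approx(res.zvalues["x"] ** 2, rel=1e-10)

    def test_lrt_close_to_wald_when_well_conditioned(self):
        rng = np.random.default_rng(8)
        q = 45  # 2025 observations
        y, X, x, ids1, ids2 = _crossed_data(8, q1=q, q2=q, slope=0.08)
        res = CrossedLMM(y, X, ids1, ids2, ["Intercept", "x"],
                         terms={"Intercept": [0], "x": [1]}).fit(n_restarts=3)
        wald = res.term_tests("wald").set_index("term").loc["x", "chi2"]
        lrt = res.term_tests("lrt").set_index("term").loc["x", "chi2"]
        assert lrt == pytest.approx(wald, rel=0.10)

    def test_standardized_beta_identity(self):
        y, X, x, ids1, ids2 = _crossed_data(9, q1=15, q2=15)
        res = CrossedLMM(y, X, ids1, ids2, ["Intercept", "x"]).fit()
        expected = res.params["x"] * x.std(ddof=1) / y.std(ddof=1)
        assert res.std_params["x"] == pytest.approx(expected, rel=1e-12)

    def test_wald_interaction_type_i_error_calibrated(self):
        """Null interaction rejected at ~5% across 400 simulated fits."""
        rejections = 0
        n_sims = 400
        for seed in range(n_sims):
            rng = np.random.default_rng(30_000 + seed)
            # two cities, 12 stations each, all within-city pairs
            frames = []
            for c, city in enumerate(("A", "B")):
                ids = [f"{city}{k}" for k in range(12)]
                rows = [(ids[i], ids[j]) for i in range(12) for j in range(i + 1, 12)]
                eff = rng.normal(0, 0.4, 12)
                x = rng.standard_normal(len(rows))
                y = (
                    0.3 * x  # same slope in both cities: interaction is null
                    + np.array([eff[int(a[1:])] + eff[int(b[1:])] for a, b in rows])
                    + rng.normal(0, 0.6, len(rows))
                )
                frames.append(
                    pd.DataFrame(
                        {
                            "station_i": [r[0] for r in rows],
                            "station_j": [r[1] for r in rows],
                            "y": y,
                            "x": x,
                            "city": city,
                        }
                    )
                )
            df = pd.concat(frames, ignore_index=True)
            res = CrossedLMM.from_pairs(df, y="y", x="x", group="city").fit(n_restarts=2)
            p = res.term_tests("wald").set_index("term").loc["x:city", "p"]
            rejections += p < 0.05
        rate = rejections / n_sims
        assert 0.035 <= rate <= 0.065

    def test_simple_slopes_single_group_equals_coefficient(self):
        y, X, x, ids1, ids2 = _crossed_data(12, q1=15, q2=15)
        df = pd.DataFrame({"station_i": ids1, "station_j": ids2, "y": y, "x": x})
        res = CrossedLMM.from_pairs(df, y="y", x="x").fit()
        slopes = res.simple_slopes()
        assert len(slopes) == 1
        assert slopes[0].slope == pytest.approx(res.params["x"], rel=1e-12)


class TestFormulaDialect:
    def test_full_mixed_formula(self):
        y, x, g, rand = parse_mixed_formula(
            "geo_km ~ ling_dist*city + (1|station_i) + (1|station_j)"
        )
        assert (y, x, g) == ("geo_km", "ling_dist", "city")
        assert rand == ["station_i", "station_j"]

    def test_unicode_variants(self):
        y, x, g, rand = parse_mixed_formula("d ~ ling×Type + (1∣s1) + (1∣s2)")
        assert (x, g) == ("ling", "Type")
        assert rand == ["s1", "s2"]

    def test_no_interaction(self):
        y, x, g, rand = parse_mixed_formula("map ~ geo + (1|a) + (1|b)")
        assert g is None

    def test_from_formula_fits(self):
        y, X, x, ids1, ids2 = _crossed_data(2, q1=10, q2=10)
        df = pd.DataFrame({"y": y, "x": x, "s1": ids1, "s2": ids2})
        res = CrossedLMM.from_formula("y ~ x + (1|s1) + (1|s2)", df).fit(n_restarts=3)
        direct = CrossedLMM(y, X, ids1, ids2).fit(n_restarts=3)
        np.testing.assert_allclose(res.params.to_numpy(), direct.params.to_numpy(), rtol=1e-8)

    def test_malformed_formula_rejected(self):
        with pytest.raises(ValueError):
            parse_mixed_formula("y ~ x + z + (1|a) + (1|b)")
        with pytest.raises(ValueError):
            parse_mixed_formula("no tilde here")

    def test_summary_renders(self):
        y, X, x, ids1, ids2 = _crossed_data(4, q1=10, q2=10)
        df = pd.DataFrame({"station_i": ids1, "station_j": ids2, "y": y, "x": x})
        res = CrossedLMM.from_pairs(df, y="y", x="x").fit(n_restarts=3)
        text = res.summary()
        assert "Variance components" in text and "REML" in text
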