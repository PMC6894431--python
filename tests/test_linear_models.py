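import numpy as np
import pandas as pd
import pytest

from oxynet.linear_models import (
    RankDeficiencyError,
    build_design,
    deviance_chisq_test,
    fit_ols,
    fit_ols_formula,
    fit_poisson,
    fit_poisson_formula,
    one_way_anova,
    sequential_f_table,
)


class TestOls:
    def test_noiseless_line(self):
        x = np.arange(5.0)
        X = np.column_stack([np.ones(5), x])
        fit = fit_ols(2 * x, X, ["Intercept", "x"])
        assert fit.params == pytest.approx([0.0, 2.0], abs=1e-12)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)

    def test_two_group_dataset_matches_normal_equations(self):
        # A: (0,0),(1,1),(2,3); B: (0,1),(1,3),(2,5) with group dummy
        df = pd.DataFrame(
            {
                "y": [0, 1, 3, 1, 3, 5],
                "x": [0, 1, 2, 0, 1, 2],
                "g": ["A", "A", "A", "B", "B", "B"],
            }
        )
        fit = fit_ols_formula(df, "y", ["x", "C(g)"])
        X, _, _ = build_design(df, ["x", "C(g)"])
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ df.y.to_numpy(float))
        assert fit.params == pytest.approx(beta_oracle, abs=1e-10)

    def test_matches_statsmodels_on_random_designs(self, rng):
        import statsmodels.api as sm

        for _ in range(15):
            n = int(rng.integers(10, 50))
            p = int(rng.integers(1, 6))
            X = np.column_stack([np.ones(n), rng.standard_normal((n, p))])
            y = rng.standard_normal(n)
            fit = fit_ols(y, X)
            ref = sm.OLS(y, X).fit()
            assert fit.params == pytest.approx(ref.params, abs=1e-8)
            assert fit.rss == pytest.approx(ref.ssr, rel=1e-10)
            assert fit.bse() == pytest.approx(ref.bse, rel=1e-8)

    def test_rank_deficiency_names_alias(self):
        df = pd.DataFrame({"y": [1.0, 2, 3, 4], "x": [1.0, 2, 3, 4]})
        df["x2"] = df.x
        with pytest.raises(RankDeficiencyError, match="x2"):
            fit_ols_formula(df, "y", ["x", "x2"])


class TestSequentialF:
    def test_pure_noise_regressor_f_near_one(self, rng):
        n, reps = 40, 400
        fs = []
        for _ in range(reps):
            df = pd.DataFrame(
                {"y": rng.standard_normal(n), "x": rng.standard_normal(n)}
            )
            fs.append(sequential_f_table(df, "y", ["x"]).F.iloc[0])
        # E[F(1, 38)] = 38/36
        assert np.mean(fs) == pytest.approx(38 / 36, abs=0.25)

    def test_duplicated_column_is_error(self):
        df = pd.DataFrame({"y": [1.0, 2, 3, 4, 5], "x": [1.0, 2, 3, 4, 5]})
        df["x2"] = df.x
        with pytest.raises((ValueError, RankDeficiencyError)):
            sequential_f_table(df, "y", ["x", "x2"])

    def test_identical_groups_zero_f(self):
        df = pd.DataFrame(
            {"y": [1.0, 2, 3, 1, 2, 3], "g": ["a"] * 3 + ["b"] * 3}
        )
        table = sequential_f_table(df, "y", ["C(g)"])
        assert table.F.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_statsmodels_anova_lm(self, rng):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols as sm_ols

        n = 30
        df = pd.DataFrame(
            {
                "y": rng.standard_normal(n),
                "x": rng.standard_normal(n),
                "g": rng.choice(["a", "b", "c"], n),
            }
        )
        # patsy orders factors before covariates, so match that entry order
        mine = sequential_f_table(df, "y", ["C(g)", "x", "x:C(g)"])
        ref = sm.stats.anova_lm(sm_ols("y ~ x + C(g) + x:C(g)", df).fit(), typ=1)
        assert mine.F.to_numpy() == pytest.approx(
            ref.F.to_numpy()[:3], rel=1e-8
        )


class TestOneWayAnova:
    def test_hand_computed_f(self):
        table = one_way_anova(
            np.array([1.0, 2, 3, 4, 5, 6]), np.array(["a"] * 3 + ["b"] * 3)
        )
        row = table.iloc[0]
        assert row.F == pytest.approx(13.5)
        assert (row.df1, row.df2) == (1, 4)

    def test_identical_groups(self):
        table = one_way_anova(
            np.array([1.0, 2, 3, 1, 2, 3]), np.array(["a"] * 3 + ["b"] * 3)
        )
        assert table.F.iloc[0] == pytest.approx(0.0)
        assert table.p.iloc[0] == pytest.approx(1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova(np.array([1.0, 2, 3]), np.array(["a"] * 3))

    def test_log1p_transform_changes_result(self):
        from oxynet.linear_models import log1p_transform

        y = np.array([13.0, 100, 900, 20, 250, 1220])
        g = np.array(["a"] * 3 + ["b"] * 3)
        raw = one_way_anova(y, g).F.iloc[0]
        logged = one_way_anova(log1p_transform(y), g).F.iloc[0]
        assert raw != pytest.approx(logged)


class TestPoisson:
    def test_intercept_only_is_log_mean(self):
        y = np.array([1, 2, 3])
        fit = fit_poisson(y, np.ones((3, 1)), ["Intercept"])
        assert fit.params[0] == pytest.approx(np.log(2), abs=1e-9)
        # closed-form deviance 2*[1*ln(1/2) + 3*ln(3/2)]
        assert fit.deviance == pytest.approx(
            2 * (np.log(0.5) + 3 * np.log(1.5)), abs=1e-9
        )

    def test_saturated_model_zero_deviance(self):
        y = np.array([1, 2, 7])
        X = np.eye(3)
        fit = fit_poisson(y, X)
        assert fit.deviance == pytest.approx(0.0, abs=1e-8)

    def test_one_parameter_matches_direct_mle(self, rng):
        # golden-section maximization of the Poisson log-likelihood
        from scipy.optimize import minimize_scalar

        y = rng.poisson(3.0, 40)
        fit = fit_poisson(y, np.ones((len(y), 1)))
        nll = lambda b: -(y * b - np.exp(b)).sum()
        ref = minimize_scalar(nll, bounds=(-5, 5), method="bounded")
        assert fit.params[0] == pytest.approx(ref.x, abs=1e-6)

    def test_matches_statsmodels_glm(self, rng):
        import statsmodels.api as sm

        n = 60
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.poisson(np.exp(0.5 + 0.3 * X[:, 1]))
        fit = fit_poisson(y, X)
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert fit.params == pytest.approx(ref.params, abs=1e-6)
        assert fit.deviance == pytest.approx(ref.deviance, rel=1e-6)

    def test_fractional_response_rejected(self):
        with pytest.raises(ValueError):
            fit_poisson(np.array([1.5, 2.0]), np.ones((2, 1)))


class TestDevianceTest:
    @staticmethod
    def _fits(df):
        reduced = fit_poisson_formula(df, "y", [])
        full = fit_poisson_formula(df, "y", ["x"])
        return reduced, full

    def test_zero_improvement_p_one(self):
        # constant response: adding the covariate cannot reduce the deviance
        df = pd.DataFrame({"y": [2, 2, 2, 2], "x": [0.0, 1.0, 2.0, 3.0]})
        reduced, full = self._fits(df)
        row = deviance_chisq_test(reduced, full, rescale=False).iloc[0]
        assert row.p == pytest.approx(1.0)

    def test_type_i_error_calibrated_when_equidispersed(self, rng):
        n, reps, alpha = 60, 800, 0.05
        rejections = 0
        for _ in range(reps):
            df = pd.DataFrame(
                {"y": rng.poisson(3.0, n), "x": rng.standard_normal(n)}
            )
            reduced, full = self._fits(df)
            row = deviance_chisq_test(reduced, full, rescale=False).iloc[0]
            rejections += row.p < alpha
        assert 0.03 <= rejections / reps <= 0.07

    def test_rescaling_is_more_conservative_when_overdispersed(self, rng):
        worse = 0
        total = 0
        for _ in range(40):
            n = 50
            lam = rng.gamma(shape=1.0, scale=3.0, size=n)  # phi ~ 1 + 3
            df = pd.DataFrame({"y": rng.poisson(lam), "x": rng.standard_normal(n)})
            reduced, full = self._fits(df)
            if full.dispersion <= 1:
                continue
            p_raw = deviance_chisq_test(reduced, full, rescale=False).p.iloc[0]
            p_scaled = deviance_chisq_test(reduced, full, rescale=True).p.iloc[0]
            total += 1
            worse += p_scaled > p_raw
        assert total > 20
        assert worse == total  # strictly less significant, every time

    def test_non_nested_rejected(self, rng):
        df = pd.DataFrame({"y": rng.poisson(2.0, 30), "x": rng.standard_normal(30)})
        reduced, full = self._fits(df)
        with pytest.raises(ValueError):
            deviance_chisq_test(full, reduced)
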