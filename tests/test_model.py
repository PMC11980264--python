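"""Quasi-Poisson fitting, design assembly and df selection."""

import numpy as np
import pandas as pd
import pytest

import thermolag as tl
from thermolag.crossbasis import build_crossbasis, spec_from_history
from thermolag.model import assemble_design, fit_quasipoisson, select_df


class TestFitQuasipoisson:
    def test_intercept_only_recovers_log_mean(self):
        y = np.array([2, 5, 3, 8, 0, 4, 6])
        fit = fit_quasipoisson(y, np.ones((7, 1)))
        assert fit.params[0] == pytest.approx(np.log(y.mean()), abs=1e-8)

    def test_binary_covariate_closed_form(self):
        rng = np.random.default_rng(0)
        g = np.repeat([0, 1], 200)
        y = rng.poisson(np.where(g == 1, 9.0, 4.0))
        design = np.column_stack([np.ones_like(g, dtype=float), g.astype(float)])
        fit = fit_quasipoisson(y, design)
        m0, m1 = y[g == 0].mean(), y[g == 1].mean()
        assert fit.params[0] == pytest.approx(np.log(m0), abs=1e-8)
        assert fit.params[1] == pytest.approx(np.log(m1 / m0), abs=1e-8)

    def test_equidispersed_poisson_gives_unit_dispersion(self):
        rng = np.random.default_rng(42)
        x = rng.normal(0, 1, 2000)
        y = rng.poisson(np.exp(1.5 + 0.3 * x))
        fit = fit_quasipoisson(y, np.column_stack([np.ones(2000), x]))
        assert 0.9 <= fit.dispersion <= 1.1

    def test_point_estimates_equal_poisson_mle(self):
        # phi rescales the covariance only
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 500)
        design = np.column_stack([np.ones(500), x])
        y = rng.negative_binomial(5, 5 / (5 + np.exp(2 + 0.4 * x)))
        fit = fit_quasipoisson(y, design)
        mle = sm.GLM(y, design, family=sm.families.Poisson()).fit()
        assert np.abs(fit.params - mle.params).max() < 1e-8
        assert np.allclose(
            fit.vcov, fit.dispersion * np.asarray(mle.cov_params()), rtol=1e-6
        )

    def test_vcov_scales_linearly_in_dispersion(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 400)
        design = np.column_stack([np.ones(400), x])
        y = rng.negative_binomial(3, 3 / (3 + np.exp(2 + 0.3 * x)))
        fit = fit_quasipoisson(y, design)
        assert np.allclose(fit.vcov / fit.dispersion * 2.0, fit.vcov * 2 / fit.dispersion)
        base = fit.vcov / fit.dispersion
        assert np.allclose(fit.vcov, fit.dispersion * base)

    def test_rank_deficiency_names_columns(self):
        x = np.random.default_rng(0).normal(0, 1, 50)
        design = np.column_stack([np.ones(50), x, 2 * x])
        with pytest.raises(ValueError, match="rank deficient"):
            fit_quasipoisson(np.ones(50, dtype=int), design, names=["c0", "a", "b"])

    def test_negative_or_fractional_outcomes_rejected(self):
        with pytest.raises(ValueError, match="non-negative integer"):
            fit_quasipoisson([1.5, 2.0], np.ones((2, 1)))
        with pytest.raises(ValueError, match="non-negative integer"):
            fit_quasipoisson([-1, 2], np.ones((2, 1)))


class TestAssembleDesign:
    def cohort(self, n=60):
        rng = np.random.default_rng(8)
        return pd.DataFrame(
            {
                "y": rng.poisson(5, n),
                "color": rng.choice(["red", "green", "blue"], n),
                "age": rng.uniform(20, 30, n),
                "flag": rng.choice(["u", "v"], n),
                "zip": rng.choice(["a", "b"], n),
            }
        )

    def test_three_level_categorical_gives_two_dummies(self):
        y, design, names, blocks = assemble_design(self.cohort(), {}, ["color"])
        assert design.shape[1] == 3  # intercept + 2 dummies
        assert blocks["color"] == slice(1, 3)

    def test_reference_level_is_most_frequent(self):
        df = self.cohort()
        ref = df["color"].value_counts().index[0]
        _, _, names, _ = assemble_design(df, {}, ["color"])
        assert all(f"vs {ref}]" in n for n in names[1:])

    def test_expected_column_count_with_crossbases(self, toy_history):
        df = self.cohort(4)
        spec = spec_from_history(toy_history, 2, 3)
        cb = build_crossbasis(toy_history, spec)
        # intercept + 2 + 1 + 1 covariate columns + two 6-column blocks = 17
        y, design, names, blocks = assemble_design(
            df, {"pre": cb, "post": cb}, ["color", "age", "flag"]
        )
        assert design.shape == (4, 17)
        assert blocks["pre"] == slice(5, 11)
        assert blocks["post"] == slice(11, 17)

    def test_empty_covariates_intercept_plus_blocks(self, toy_history):
        spec = spec_from_history(toy_history)
        cb = build_crossbasis(toy_history, spec)
        _, design, _, blocks = assemble_design(self.cohort(4), {"pre": cb})
        assert design.shape[1] == 1 + 6
        assert blocks["intercept"] == slice(0, 1)

    def test_missing_covariate_values_rejected(self):
        df = self.cohort()
        df.loc[0, "age"] = np.nan
        with pytest.raises(ValueError, match="'age'.*impute"):
            assemble_design(df, {}, ["age"])


class TestSelectDf:
    def _histories(self, n=800, seed=11):
        truth = tl.postnatal_heat_hump_truth()
        cohort, daily = tl.simulate_cohort(n, truth, seed=seed)
        anchors_c = pd.Series(
            cohort["conception_date"].to_numpy(), index=cohort["subject_id"].to_numpy()
        )
        anchors_b = pd.Series(
            cohort["birth_date"].to_numpy(), index=cohort["subject_id"].to_numpy()
        )
        hist = {
            "pre": tl.build_history(daily, anchors_c, "prenatal"),
            "post": tl.build_history(daily, anchors_b, "postnatal"),
        }
        return cohort, hist

    def test_single_candidate_returned_unchanged(self):
        cohort, hist = self._histories(n=300)
        chosen, table = select_df(cohort, hist, [(2, 3)], covariates=["sex"])
        assert len(table) == 1
        assert chosen["pre"].df_var == 2 and chosen["pre"].df_lag == 3

    def test_table_has_one_row_per_candidate(self):
        cohort, hist = self._histories(n=300)
        cands = [(1, 2), (2, 3), (3, 4)]
        _, table = select_df(cohort, hist, cands, covariates=["sex"])
        assert len(table) == len(cands)
        assert {"df_var", "df_lag", "qaic"} <= set(table.columns)

    def test_generating_df_pair_preferred_over_richer(self):
        # data generated from a (2,3)-representable surface: QAIC should
        # prefer (2,3) to the overparameterised (4,6) in most replicates
        wins = 0
        for seed in range(6):
            cohort, hist = self._histories(n=1200, seed=100 + seed)
            chosen, _ = select_df(
                cohort, hist, [(2, 3), (4, 6)], covariates=["sex", "edu"]
            )
            if (chosen["pre"].df_var, chosen["pre"].df_lag) == (2, 3):
                wins += 1
        assert wins >= 5
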