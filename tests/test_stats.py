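import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from limbuse.io import ValidationError
from limbuse.stats import (
    DegenerateInputError,
    covariate_adjusted_contrast,
    fisher_compare,
    gated_two_sample,
    mixed_anova,
    one_sample_vs_zero,
    partial_corr,
    pearson_corr,
    planned_comparisons,
)

from . import oracles


class TestGatedTwoSample:
    def test_identical_samples_t_zero_p_one(self):
        res = gated_two_sample([1, 2, 3, 4, 5], [1, 2, 3, 4, 5], force_branch="parametric")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.test_name == "t_independent"

    def test_complete_separation_gives_minimal_u(self):
        res = gated_two_sample([1, 2, 3], [4, 5, 6], force_branch="nonparametric")
        assert res.test_name == "mann_whitney_u"
        assert res.statistic == 0.0

    def test_t_matches_pooled_formula(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.4, 1.3, 9)
        res = gated_two_sample(a, b, force_branch="parametric")
        t, df = oracles.t_pooled(a, b)
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.df == df
        assert res.p_value == pytest.approx(2 * sps.t.sf(abs(t), df), abs=1e-10)

    def test_u_matches_pair_counting(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 9)
        res = gated_two_sample(a, b, force_branch="nonparametric")
        assert res.statistic == pytest.approx(oracles.mann_whitney_u(a, b))
        assert res.extra["mw_method"] == "exact"

    def test_branch_is_function_of_shapiro_pvalues(self, rng):
        normal = rng.normal(0, 1, 25)
        skewed = rng.exponential(1, 25) ** 3
        res = gated_two_sample(normal, skewed)
        assert res.extra["branch"] == "nonparametric"
        assert res.extra["shapiro_p_b"] <= 0.05
        res2 = gated_two_sample(normal, rng.normal(2, 1, 25))
        if res2.extra["shapiro_p_a"] > 0.05 and res2.extra["shapiro_p_b"] > 0.05:
            assert res2.extra["branch"] == "parametric"

    def test_zero_variance_t_branch_degenerate(self):
        with pytest.raises(DegenerateInputError):
            gated_two_sample([1, 1, 1, 1], [1, 1, 1, 1], force_branch="parametric")

    def test_too_small_group_rejected(self):
        with pytest.raises(ValidationError):
            gated_two_sample([1, 2], [1, 2, 3])


class TestOneSample:
    def test_symmetric_sample_t_zero(self):
        res = one_sample_vs_zero([-2, -1, 0, 1, 2])
        assert res.statistic == pytest.approx(0.0)

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateInputError):
            one_sample_vs_zero([1.0, 1.0, 1.0, 1.0])

    def test_matches_closed_form(self, rng):
        x = rng.normal(0.3, 1.0, 17)
        res = one_sample_vs_zero(x)
        t, df = oracles.t_one_sample(x)
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.df == df


class TestMixedAnova:
    def test_null_interaction_constructed_zero(self):
        # identical limb-difference profile in every group: cell means carry
        # group and limb effects but their interaction is exactly 0
        groups = np.repeat(["a", "b"], 6)
        base = np.arange(12, dtype=float)
        pattern = np.tile([-1.0, 0.0, 1.0, 2.0, -2.0, 0.0], 2)  # same per group
        y1 = base + (groups == "b") * 2.0
        y2 = y1 + 1.5 + pattern
        res = mixed_anova(groups, y1, y2)
        assert res.statistic == pytest.approx(0.0, abs=1e-20)

    def test_balanced_toy_matches_ss_oracle(self, rng):
        groups = np.repeat(["a", "b", "c"], 4)
        y1 = rng.normal(0, 1, 12) + (groups == "a") * 1.0
        y2 = rng.normal(0, 1, 12) - (groups == "c") * 0.5
        res = mixed_anova(groups, y1, y2)
        f, (df1, df2) = oracles.splitplot_interaction_f(groups, y1, y2)
        assert res.statistic == pytest.approx(f, abs=1e-10)
        assert res.df == (df1, df2)

    def test_unbalanced_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        groups = np.repeat(["a", "b", "c"], [5, 8, 6])
        n = len(groups)
        y1 = rng.normal(0, 1, n) + (groups == "b") * 0.5
        y2 = rng.normal(0, 1, n) - (groups == "c") * 0.7
        res = mixed_anova(groups, y1, y2)
        long = pd.DataFrame({
            "subj": np.tile(np.arange(n), 2),
            "group": np.tile(groups, 2),
            "limb": np.repeat(["l1", "l2"], n),
            "y": np.concatenate([y1, y2]),
        })
        tab = pg.mixed_anova(data=long, dv="y", within="limb", subject="subj", between="group")
        row = tab[tab.Source == "Interaction"].iloc[0]
        assert res.statistic == pytest.approx(row.F, abs=1e-8)
        assert res.p_value == pytest.approx(row.p_unc, abs=1e-8)
        assert res.df == (row.DF1, row.DF2)

    def test_missing_cell_lists_participants(self):
        groups = ["a", "a", "b", "b"]
        with pytest.raises(ValidationError, match="P3"):
            mixed_anova(groups, [1, 2, 3, 4], [1, 2, np.nan, 4],
                        participant_ids=["P1", "P2", "P3", "P4"])


class TestCovariateContrast:
    def test_constant_covariate_is_rank_deficient(self, rng):
        y = rng.normal(0, 1, 10)
        g = np.repeat(["a", "b"], 5)
        cov = pd.DataFrame({"c": np.ones(10)})
        with pytest.raises(ValidationError, match="collinear"):
            covariate_adjusted_contrast(y, g, cov)

    def test_empty_covariates_reproduce_unadjusted_contrast(self, rng):
        y = rng.normal(0, 1, 14)
        g = np.repeat(["a", "b"], 7)
        res = covariate_adjusted_contrast(y, g, None)
        t = gated_two_sample(y[:7], y[7:], force_branch="parametric")
        assert res.statistic == pytest.approx(t.statistic**2, abs=1e-10)
        assert res.df == (1.0, 12.0)

    def test_toy_dataset_matches_nested_rss_oracle(self, rng):
        y = rng.normal(0, 1, 8)
        g = np.array(["a", "b"] * 4)
        cov = pd.DataFrame({"c1": rng.normal(0, 1, 8), "c2": rng.normal(0, 1, 8)})
        res = covariate_adjusted_contrast(y, g, cov)
        n = 8
        dummy = (g == "b").astype(float)
        x_red = np.column_stack([np.ones(n), cov.to_numpy()])
        x_full = np.column_stack([x_red, dummy])
        f, (df1, df2) = oracles.nested_f(y, x_full, x_red)
        assert res.statistic == pytest.approx(f, abs=1e-10)
        assert res.df == (df1, df2)

    def test_group_effect_zero_when_dependent_is_covariate(self):
        cov = pd.DataFrame({"c": np.arange(10.0)})
        y = 2.0 * cov["c"].to_numpy() + 1.0
        g = np.array(["a", "b"] * 5)
        res = covariate_adjusted_contrast(y, g, cov)
        assert res.statistic == pytest.approx(0.0, abs=1e-16)


class TestCorrelations:
    def test_exact_linearity(self):
        x = np.arange(10.0)
        assert pearson_corr(x, 2 * x + 3).statistic == pytest.approx(1.0)
        assert pearson_corr(x, -x).statistic == pytest.approx(-1.0)

    def test_pearson_matches_covariance_formula(self, rng):
        x, y = rng.normal(0, 1, 23), rng.normal(0, 1, 23)
        res = pearson_corr(x, y)
        r = oracles.pearson_r(x, y)
        assert res.statistic == pytest.approx(r, abs=1e-10)
        t = r * math.sqrt(21 / (1 - r * r))
        assert res.p_value == pytest.approx(2 * sps.t.sf(abs(t), 21), abs=1e-10)
        assert res.df == 21

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson_corr([1, 1, 1, 1], [1, 2, 3, 4])

    def test_partial_equals_pearson_under_orthogonal_nuisance(self, rng):
        n = 40
        x, y = rng.normal(0, 1, n), rng.normal(0, 1, n)
        z = rng.normal(0, 1, n)
        # orthogonalize z against x and y (and the intercept)
        basis = np.column_stack([np.ones(n), x, y])
        z = z - basis @ np.linalg.lstsq(basis, z, rcond=None)[0]
        res = partial_corr(x, y, z, tails="two")
        assert res.statistic == pytest.approx(pearson_corr(x, y).statistic, abs=1e-10)

    def test_nuisance_equal_to_x_rejected(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(0, 1, 10)
        with pytest.raises(ValidationError, match="coincides"):
            partial_corr(x, y, x.copy())

    def test_toy_matches_precision_matrix_oracle(self, rng):
        n = 6
        x, y = rng.normal(0, 1, n), rng.normal(0, 1, n)
        z = rng.normal(0, 1, (n, 2))
        res = partial_corr(x, y, z, tails="two")
        assert res.statistic == pytest.approx(oracles.partial_r_precision(x, y, z), abs=1e-10)
        assert res.df == n - 2 - 2

    def test_one_tailed_direction_halves_p_on_that_side(self, rng):
        n = 20
        x = rng.normal(0, 1, n)
        y = -x + rng.normal(0, 1, n)
        z = rng.normal(0, 1, n)
        two = partial_corr(x, y, z, tails="two")
        one = partial_corr(x, y, z, tails="one", direction="negative")
        assert one.p_value == pytest.approx(two.p_value / 2, abs=1e-12)

    def test_undeclared_direction_falls_back_to_two_tailed(self, rng, caplog):
        x, y, z = rng.normal(0, 1, (3, 15))
        with caplog.at_level("WARNING"):
            res = partial_corr(x, y, z, tails="one", direction=None)
        assert res.tails == "two"
        assert "direction" in caplog.text

    def test_pingouin_cross_check(self, rng):
        pg = pytest.importorskip("pingouin")
        n = 30
        x, y, z = rng.normal(0, 1, (3, n))
        res = partial_corr(x, y, z, tails="two")
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        out = pg.partial_corr(data=df, x="x", y="y", covar="z")
        assert res.statistic == pytest.approx(float(out["r"].iloc[0]), abs=1e-8)
        assert res.p_value == pytest.approx(float(out["p_val"].iloc[0]), abs=1e-8)


class TestFisherCompare:
    def test_equal_correlations_z_zero(self):
        res = fisher_compare(0.4, 15, 0.4, 15)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_closed_form(self):
        res = fisher_compare(0.5, 20, 0.0, 20)
        assert res.statistic == pytest.approx(oracles.fisher_z(0.5, 20, 0.0, 20), abs=1e-12)

    def test_swap_flips_sign_same_p(self):
        a = fisher_compare(0.6, 25, -0.1, 40)
        b = fisher_compare(-0.1, 40, 0.6, 25)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_perfect_correlation_rejected(self):
        with pytest.raises(DegenerateInputError):
            fisher_compare(1.0, 10, 0.0, 10)


class TestPlannedComparisons:
    @staticmethod
    def _frame(rng):
        g = np.repeat(["congenital", "acquired", "control"], 10)
        return pd.DataFrame({"group": g, "v": rng.normal(0, 1, 30)})

    def test_alpha_bookkeeping(self, rng):
        df = self._frame(rng)
        plan = [
            {"name": "p1", "column": "v", "group_a": "congenital", "group_b": "acquired",
             "planned": True},
            {"name": "e1", "column": "v", "group_a": "congenital", "group_b": "control"},
        ]
        res = planned_comparisons(df, plan)
        assert [r.alpha_used for r in res] == [0.025, 0.05]
        # threshold logic: p = 0.03 is significant only at alpha 0.05
        for r, alpha in zip(res, (0.025, 0.05)):
            expected = "significant" if r.p_value <= alpha else "not_significant"
            assert r.decision == expected

    def test_unknown_group_rejected(self, rng):
        df = self._frame(rng)
        with pytest.raises(ValidationError, match="unknown group"):
            planned_comparisons(df, [{"name": "x", "column": "v",
                                      "group_a": "congenital", "group_b": "amputee"}])

    def test_four_contrast_plan_returns_four_results(self, rng):
        df = self._frame(rng)
        plan = [{"name": f"c{i}", "column": "v", "group_a": "congenital",
                 "group_b": "acquired", "planned": i < 2} for i in range(4)]
        res = planned_comparisons(df, plan)
        assert len(res) == 4
        assert [r.extra["planned"] for r in res] == [True, True, False, False]

    def test_missing_values_excluded_and_counted(self, rng):
        df = self._frame(rng)
        df.loc[0, "v"] = np.nan
        res = planned_comparisons(df, [{"name": "c", "column": "v",
                                        "group_a": "congenital", "group_b": "acquired"}])[0]
        assert res.extra["n_excluded"] == 1
        assert res.n == (9, 10)
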