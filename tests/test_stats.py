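import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from iscn.errors import DegenerateInputError, ValidationError
from iscn.stats import (
    ancova_per_index,
    bootstrap_partial_correlation,
    compare_global,
    compare_nodal,
    correlation_screen,
    fdr_adjust,
    lsd_posthoc,
    manova_pretest,
    partial_correlation,
)

from .oracles import anova_F_loop, bh_loop, partial_corr_loop


def _three_groups(rng, n=20, shift=(0.0, 0.0, 0.0)):
    groups = np.repeat(["a", "b", "c"], n)
    y = rng.standard_normal(3 * n) + np.repeat(shift, n)
    cov = rng.standard_normal(3 * n)
    return y, groups, cov


class TestAncova:
    @pytest.mark.parametrize("covariate", ["zero", "none"])
    def test_null_covariate_reduces_to_anova(self, rng, covariate):
        y, groups, _ = _three_groups(rng)
        cov = np.zeros_like(y) if covariate == "zero" else None
        res = ancova_per_index(y, groups, cov)
        assert res.F == pytest.approx(anova_F_loop(y, np.asarray(groups)), abs=1e-10)
        f, p = sps.f_oneway(*(y[groups == g] for g in "abc"))
        assert res.F == pytest.approx(f, abs=1e-10)
        assert res.p_raw == pytest.approx(p, abs=1e-12)

    def test_matches_statsmodels_type2(self, rng):
        y, groups, cov = _three_groups(rng, shift=(0, 0.3, 0.8))
        res = ancova_per_index(y, groups, cov)
        df = pd.DataFrame({"y": y, "g": groups, "cov": cov})
        fit = ols("y ~ C(g) + cov", data=df).fit()
        table = anova_lm(fit, typ=2)
        assert res.F == pytest.approx(table.loc["C(g)", "F"], rel=1e-10)
        assert res.p_raw == pytest.approx(table.loc["C(g)", "PR(>F)"], rel=1e-8)
        eta = table.loc["C(g)", "sum_sq"] / (
            table.loc["C(g)", "sum_sq"] + table.loc["Residual", "sum_sq"]
        )
        assert res.partial_eta_squared == pytest.approx(eta, rel=1e-10)

    def test_type_one_error_calibrated(self, rng):
        """Permuting labels under the null keeps p approximately uniform."""
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            y, groups, cov = _three_groups(rng, n=15)
            res = ancova_per_index(y, rng.permutation(groups), cov)
            hits += res.p_raw < 0.05
        assert hits / n_sim < 0.10  # 5% nominal, binomial slack

    def test_power_for_one_sd_shift(self, rng):
        detected = 0
        for _ in range(50):
            y, groups, cov = _three_groups(rng, n=36, shift=(0.0, 0.0, 1.0))
            res = ancova_per_index(y, groups, cov)
            detected += res.p_raw < 0.05
        assert detected / 50 >= 0.8

    def test_constant_outcome_rejected(self):
        with pytest.raises(DegenerateInputError, match="constant"):
            ancova_per_index(np.ones(12), np.repeat(["a", "b"], 6), None)

    def test_collinear_covariate_rejected(self, rng):
        y, groups, _ = _three_groups(rng, n=5)
        indicator = (np.asarray(groups) == "a").astype(float)
        with pytest.raises(DegenerateInputError, match="rank"):
            ancova_per_index(y, groups, indicator)

    def test_tiny_group_rejected(self, rng):
        y = rng.standard_normal(5)
        with pytest.raises(DegenerateInputError, match="fewer than 2"):
            ancova_per_index(y, ["a", "a", "a", "a", "b"], None)


class TestFdrAdjust:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(
            fdr_adjust([0.005, 0.03, 0.04]), [0.015, 0.04, 0.04]
        )

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.2, 0.2, 0.2, 0.2]), 0.2)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.031]), [0.031])

    def test_matches_step_up_oracle_and_statsmodels(self, rng):
        for _ in range(20):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            ours = fdr_adjust(p)
            np.testing.assert_allclose(ours, bh_loop(p.tolist()), atol=1e-12)
            _, sm, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(ours, sm, atol=1e-12)

    def test_monotone_and_dominates_raw(self, rng):
        p = rng.uniform(size=25)
        adj = fdr_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            fdr_adjust([0.5, 1.2])


class TestLsdPosthoc:
    def test_two_groups_pairwise_equals_omnibus(self, rng):
        y = rng.standard_normal(30)
        groups = np.repeat(["a", "b"], 15)
        cov = rng.standard_normal(30)
        omnibus = ancova_per_index(y, groups, cov)
        (pair,) = lsd_posthoc(y, groups, cov)
        assert pair.t**2 == pytest.approx(omnibus.F, rel=1e-10)
        assert pair.p == pytest.approx(omnibus.p_raw, rel=1e-10)

    def test_identical_means_rarely_significant(self, rng):
        sig = 0
        for _ in range(100):
            y, groups, cov = _three_groups(rng, n=12)
            sig += any(r.p < 0.05 for r in lsd_posthoc(y, groups, cov))
        # three unadjusted tests -> ~14% familywise at the null
        assert sig / 100 < 0.25

    def test_shifted_third_group_detected(self, rng):
        y = np.concatenate(
            [
                0.1 * rng.standard_normal(12),
                0.1 * rng.standard_normal(12),
                1.0 + 0.1 * rng.standard_normal(12),
            ]
        )
        groups = np.repeat(["a", "b", "c"], 12)
        res = {r.pair: r.p for r in lsd_posthoc(y, groups, None)}
        assert res[("a", "b")] > 0.05
        assert res[("a", "c")] < 0.001
        assert res[("b", "c")] < 0.001

    def test_adjusted_mean_difference_matches_statsmodels(self, rng):
        y, groups, cov = _three_groups(rng, shift=(0, 0.5, 1.0))
        df = pd.DataFrame({"y": y, "g": groups, "cov": cov})
        fit = ols("y ~ C(g) + cov", data=df).fit()
        results = lsd_posthoc(y, groups, cov)
        ab = next(r for r in results if r.pair == ("a", "b"))
        assert ab.mean_difference == pytest.approx(
            -fit.params["C(g)[T.b]"], rel=1e-10
        )
        tt = fit.t_test("C(g)[T.b] = 0")
        assert abs(ab.t) == pytest.approx(abs(float(np.squeeze(tt.tvalue))), rel=1e-10)
        assert ab.p == pytest.approx(float(np.squeeze(tt.pvalue)), rel=1e-8)


class TestCompareFamilies:
    def test_posthoc_only_where_fdr_significant(self, rng):
        table = pd.DataFrame(
            {
                "null1": rng.standard_normal(60),
                "null2": rng.standard_normal(60),
                "effect": np.repeat([0.0, 0.0, 2.0], 20) + 0.3 * rng.standard_normal(60),
            }
        )
        groups = np.repeat(["a", "b", "c"], 20)
        results = compare_global(table, groups, rng.standard_normal(60))
        by_name = {r.index_name: r for r in results}
        assert by_name["effect"].p_fdr < 0.05 and by_name["effect"].posthoc
        assert not by_name["null1"].posthoc

    def test_fdr_family_is_all_columns(self, rng):
        table = pd.DataFrame(rng.standard_normal((40, 4)), columns=list("wxyz"))
        groups = np.repeat(["a", "b"], 20)
        results = compare_global(table, groups, None)
        raw = [r.p_raw for r in results]
        np.testing.assert_allclose(
            [r.p_fdr for r in results], fdr_adjust(raw), atol=1e-12
        )

    def test_constant_region_excluded_with_reduced_family(self, rng):
        table = pd.DataFrame(rng.standard_normal((30, 5)), columns=list("abcde"))
        table["c"] = 1.0
        groups = np.repeat(["x", "y", "z"], 10)
        results, excluded = compare_nodal(table, groups, None)
        assert excluded == ["c"]
        assert len(results) == 4
        raw = [r.p_raw for r in results]
        np.testing.assert_allclose([r.p_fdr for r in results], fdr_adjust(raw))

    def test_manova_pretest_matches_statsmodels(self, rng):
        from statsmodels.multivariate.manova import MANOVA

        table = pd.DataFrame(
            rng.standard_normal((45, 3)) + np.repeat([0, 0.4, 0.8], 15)[:, None],
            columns=["m1", "m2", "m3"],
        )
        groups = np.repeat(["a", "b", "c"], 15)
        cov = rng.standard_normal(45)
        lam, F, p = manova_pretest(table, groups, cov)
        df = table.assign(g=groups, cov=cov)
        fit = MANOVA.from_formula("m1 + m2 + m3 ~ C(g) + cov", data=df)
        sm = fit.mv_test().results["C(g)"]["stat"]
        assert lam == pytest.approx(sm.loc["Wilks' lambda", "Value"], rel=1e-8)
        assert F == pytest.approx(sm.loc["Wilks' lambda", "F Value"], rel=1e-6)
        assert p == pytest.approx(sm.loc["Wilks' lambda", "Pr > F"], rel=1e-6, abs=1e-12)


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self, rng):
        x, y = rng.standard_normal((2, 25))
        res = partial_correlation(x, y)
        r, p = sps.pearsonr(x, y)
        assert res.r == pytest.approx(r, abs=1e-12)
        assert res.p_parametric == pytest.approx(p, abs=1e-10)

    def test_identical_variables_give_unit_r(self, rng):
        x = rng.standard_normal(20)
        Z = rng.standard_normal((20, 2))
        res = partial_correlation(x, x.copy(), Z)
        assert res.r == pytest.approx(1.0)

    def test_matches_residual_oracle_and_pingouin(self, rng):
        for _ in range(10):
            x, y = rng.standard_normal((2, 30))
            Z = rng.standard_normal((30, 2))
            res = partial_correlation(x, y, Z)
            assert res.r == pytest.approx(partial_corr_loop(x, y, Z), abs=1e-10)
            df = pd.DataFrame({"x": x, "y": y, "z1": Z[:, 0], "z2": Z[:, 1]})
            pgres = pg.partial_corr(df, x="x", y="y", covar=["z1", "z2"])
            assert res.r == pytest.approx(float(pgres["r"].iloc[0]), abs=1e-10)
            assert res.p_parametric == pytest.approx(
                float(pgres["p_val"].iloc[0]), rel=1e-6
            )

    def test_insufficient_n_rejected(self, rng):
        with pytest.raises(DegenerateInputError, match="covariates"):
            partial_correlation(
                rng.standard_normal(4), rng.standard_normal(4), rng.standard_normal((4, 2))
            )


class TestBootstrap:
    def test_same_seed_identical_interval(self, rng):
        x, y = rng.standard_normal((2, 30))
        a = bootstrap_partial_correlation(x, y, n_boot=300, seed=42)
        b = bootstrap_partial_correlation(x, y, n_boot=300, seed=42)
        assert (a.ci_low, a.ci_high, a.p_bootstrap) == (b.ci_low, b.ci_high, b.p_bootstrap)

    def test_different_seed_differs(self, rng):
        x, y = rng.standard_normal((2, 30))
        a = bootstrap_partial_correlation(x, y, n_boot=300, seed=1)
        b = bootstrap_partial_correlation(x, y, n_boot=300, seed=2)
        assert (a.ci_low, a.ci_high) != (b.ci_low, b.ci_high)

    def test_perfect_correlation_collapses_interval(self, rng):
        x = rng.standard_normal(25)
        res = bootstrap_partial_correlation(x, x.copy(), n_boot=200, seed=0)
        assert res.ci_low == pytest.approx(1.0)
        assert res.ci_high == pytest.approx(1.0)

    def test_interval_contains_point_estimate(self, rng):
        for _ in range(5):
            x, y = rng.standard_normal((2, 40))
            res = bootstrap_partial_correlation(x, y, n_boot=400, seed=7)
            assert res.ci_low <= res.r <= res.ci_high

    def test_null_coverage(self, rng):
        """~95% of 95% intervals on independent data should cover zero."""
        covered = 0
        n_sim = 100
        for _ in range(n_sim):
            x, y = rng.standard_normal((2, 39))
            res = bootstrap_partial_correlation(x, y, n_boot=200, seed=int(rng.integers(2**31)))
            covered += res.ci_low <= 0 <= res.ci_high
        assert covered / n_sim >= 0.85


class TestCorrelationScreen:
    def test_per_group_covariates_and_missing_scores(self, rng):
        n = 60
        groups = np.repeat(["patient", "control"], 30)
        indices = pd.DataFrame({"strength": rng.standard_normal(n)})
        scores = pd.DataFrame({"symptom": rng.standard_normal(n)})
        scores.loc[groups == "control", "symptom"] = np.nan
        covs = pd.DataFrame({"dose": rng.standard_normal(n)})
        results = correlation_screen(
            indices, scores, groups,
            {"patient": ["dose"], "control": []},
            covariate_table=covs, n_boot=100, seed=5,
        )
        assert len(results) == 1  # control screen skipped: all scores missing
        assert results[0].group == "patient"
        assert results[0].covariates == ["dose"]
        assert results[0].n == 30

    def test_screen_deterministic_given_seed(self, rng):
        n = 40
        groups = np.repeat(["p", "q"], 20)
        indices = pd.DataFrame({"i": rng.standard_normal(n)})
        scores = pd.DataFrame({"s": rng.standard_normal(n)})
        a = correlation_screen(indices, scores, groups, {}, n_boot=100, seed=9)
        b = correlation_screen(indices, scores, groups, {}, n_boot=100, seed=9)
        assert [(r.ci_low, r.ci_high) for r in a] == [(r.ci_low, r.ci_high) for r in b]

    def test_tiny_group_raises(self, rng):
        """n = 3 with two covariates violates n > #covariates + 2."""
        groups = np.array(["p"] * 3 + ["q"] * 20)
        indices = pd.DataFrame({"i": rng.standard_normal(23)})
        scores = pd.DataFrame({"s": rng.standard_normal(23)})
        covs = pd.DataFrame(
            {"dose": rng.standard_normal(23), "duration": rng.standard_normal(23)}
        )
        with pytest.raises(DegenerateInputError):
            correlation_screen(
                indices, scores, groups,
                {"p": ["dose", "duration"], "q": ["dose", "duration"]},
                covariate_table=covs, n_boot=50, seed=1,
            )
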