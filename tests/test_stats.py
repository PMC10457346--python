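"""Inference layer: sphericity handling, interaction scans, partial
correlations, Fisher comparisons, multiplicity, group comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from amynet.stats import (
    adjust_pvalues,
    compare_correlations,
    gg_epsilon,
    group_compare,
    group_partial_correlations,
    interaction_scan,
    mauchly_test,
    partial_correlation,
    per_cost_interaction,
    pooled_t_from_summary,
    rm_ancova,
    within_contrasts,
)
from amynet.synthetic import SyntheticConfig, generate_metric_table


def toy_pheno(rng, n=40, seed_frac=0.4):
    g = (np.arange(n) < int(n * seed_frac)).astype(int)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "abeta_positive": g,
            "memory": rng.normal(12, 2, n),
            "age": rng.normal(72, 6, n),
            "sex": rng.integers(0, 2, n),
            "education": rng.normal(16, 2, n),
        }
    )


class TestSphericity:
    def test_exact_compound_symmetry_gives_epsilon_one(self):
        p = 7
        M = within_contrasts(p)
        sigma = 0.4 * np.eye(p) + 0.6  # exactly compound symmetric
        S = M.T @ sigma @ M
        assert gg_epsilon(S) == pytest.approx(1.0, abs=1e-12)
        W, pval = mauchly_test(S, df_error=60)
        assert W == pytest.approx(1.0, abs=1e-12) and pval == pytest.approx(1.0)

    def test_two_levels_epsilon_always_one(self):
        S = np.array([[2.7]])
        assert gg_epsilon(S) == 1.0
        assert mauchly_test(S, df_error=30) == (1.0, 1.0)

    def test_fixture_covariance_matches_textbook_formula(self):
        p = 4
        M = within_contrasts(p)
        sigma = np.array(
            [[4.0, 1.0, 0.5, 0.2],
             [1.0, 3.0, 0.8, 0.4],
             [0.5, 0.8, 2.0, 0.6],
             [0.2, 0.4, 0.6, 1.5]]
        )
        S = M.T @ sigma @ M
        d = p - 1
        eps_direct = np.trace(S) ** 2 / (d * np.trace(S @ S))
        assert gg_epsilon(S) == pytest.approx(eps_direct)
        W_direct = np.linalg.det(S) / (np.trace(S) / d) ** d
        W, _ = mauchly_test(S, df_error=50)
        assert W == pytest.approx(W_direct)

    def test_epsilon_clipped_to_lower_bound(self):
        # rank-1-dominated contrast covariance pushes epsilon to 1/(p-1)
        d = 6
        S = np.full((d, d), 0.999) + 0.001 * np.eye(d)
        assert gg_epsilon(S) >= 1.0 / d

    def test_matches_pingouin_on_long_data(self, rng):
        pg = pytest.importorskip("pingouin")
        n, p = 25, 4
        data = rng.normal(size=(n, p)) @ rng.normal(size=(p, p))
        M = within_contrasts(p)
        # one-sample setting: residual covariance after removing the mean
        S = M.T @ np.cov(data, rowvar=False) @ M
        long = pd.DataFrame(
            {
                "y": data.ravel(),
                "subject": np.repeat(np.arange(n), p),
                "within": np.tile(np.arange(p), n),
            }
        )
        eps_pg = float(pg.epsilon(long, dv="y", subject="subject",
                                  within="within", correction="gg"))
        assert gg_epsilon(S) == pytest.approx(eps_pg, abs=1e-8)
        spher = pg.sphericity(long, dv="y", subject="subject", within="within")
        W, pval = mauchly_test(S, df_error=n - 1)
        assert W == pytest.approx(spher.W, abs=1e-8)
        assert pval == pytest.approx(spher.pval, abs=1e-6)


class TestRmAncova:
    def test_compound_symmetric_simulation_keeps_sphericity(self):
        cfg = SyntheticConfig(seed=21)
        wide, ph, _ = generate_metric_table(cfg)
        res = {e.effect: e for e in rm_ancova(wide, ph, predictor="memory")}
        cost = res["cost"]
        # CS population covariance: Mauchly rarely rejects, epsilon near 1
        assert cost.gg_epsilon > 0.8
        assert not cost.corrected or cost.mauchly_p < 0.05
        assert cost.p_gg >= cost.p_uncorrected  # GG never anticonservative

    def test_single_cost_reduces_to_ols_ancova(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        ph = toy_pheno(rng, n=50)
        y = rng.normal(size=50) + 0.5 * ph["memory"]
        wide = pd.DataFrame({0.25: y.to_numpy()}, index=ph["subject_id"])
        res = {e.effect: e for e in rm_ancova(wide, ph, predictor="memory")}
        assert all("cost" not in k for k in res)  # no within terms at 1 level
        g = 2.0 * ph["abeta_positive"] - 1
        x = ph["memory"] - ph["memory"].mean()
        X = np.column_stack(
            [np.ones(50), g, x, g * x,
             ph["age"] - ph["age"].mean(),
             ph["sex"] - ph["sex"].mean(),
             ph["education"] - ph["education"].mean()]
        )
        fit = sm.OLS(y.to_numpy(), X).fit()
        assert res["memory"].F == pytest.approx(fit.tvalues[2] ** 2, rel=1e-8)
        assert res["abeta_positive_x_memory"].p == pytest.approx(fit.pvalues[3], rel=1e-8)

    def test_planted_interaction_is_detected(self):
        cfg = SyntheticConfig(seed=77, beta_interaction=1.5)
        wide, ph, _ = generate_metric_table(cfg)
        res = {e.effect: e for e in rm_ancova(wide, ph, predictor="memory")}
        assert res["abeta_positive_x_memory"].p < 0.01

    def test_rank_deficient_design_names_columns(self, rng):
        ph = toy_pheno(rng, n=30)
        ph["education"] = ph["age"] * 2.0  # exact collinearity
        wide = pd.DataFrame(
            rng.normal(size=(30, 3)), index=ph["subject_id"], columns=[0.1, 0.2, 0.3]
        )
        with pytest.raises(ValueError, match="collinear"):
            rm_ancova(wide, ph, predictor="memory")


class TestPerCostInteraction:
    def test_matches_statsmodels_ols(self):
        sm = pytest.importorskip("statsmodels.api")
        ph = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(8)],
                "abeta_positive": [0, 1, 0, 1, 0, 1, 0, 1],
                "memory": [10.0, 14.0, 11.5, 9.0, 13.0, 15.5, 8.0, 12.0],
                "age": [70.0, 75.0, 68.0, 72.0, 80.0, 66.0, 74.0, 71.0],
                "sex": [0, 1, 1, 0, 0, 1, 0, 1],
                "education": [16.0, 12.0, 18.0, 14.0, 16.0, 20.0, 13.0, 17.0],
            }
        )
        y = np.array([0.3, 0.9, 0.4, 0.5, 0.2, 1.1, 0.35, 0.8])
        t, p = per_cost_interaction(y, ph)
        x = ph["memory"] - ph["memory"].mean()
        X = np.column_stack(
            [np.ones(8), ph["abeta_positive"], x, ph["abeta_positive"] * x,
             ph["age"], ph["sex"], ph["education"]]
        )
        fit = sm.OLS(y, X).fit()
        assert t == pytest.approx(fit.tvalues[3], abs=1e-8)
        assert p == pytest.approx(fit.pvalues[3], abs=1e-8)

    def test_power_on_planted_interaction(self, rng):
        """A planted group-specific slope (0.8 in the positive group, 0 in
        the negative, low noise) is detected in >= 90% of 200 replicates."""
        hits = 0
        reps = 200
        for _ in range(reps):
            ph = toy_pheno(rng, n=65, seed_frac=21 / 65)
            y = (
                0.8 * ph["abeta_positive"] * (ph["memory"] - ph["memory"].mean())
                + rng.normal(0, 1.0, 65)
            ).to_numpy()
            _, p = per_cost_interaction(y, ph)
            hits += p < 0.05
        assert hits / reps >= 0.90

    def test_permutation_null_is_calibrated(self):
        rng = np.random.default_rng(4)
        cfg = SyntheticConfig(seed=8, beta_interaction=1.5)
        wide, ph, _ = generate_metric_table(cfg)
        y = wide[0.25].to_numpy()
        hits = 0
        reps = 300
        for _ in range(reps):
            shuffled = ph.copy()
            shuffled["memory"] = rng.permutation(ph["memory"].to_numpy())
            _, p = per_cost_interaction(y, shuffled)
            hits += p < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.035)

    def test_constant_metric_is_error(self, rng):
        ph = toy_pheno(rng, n=20)
        with pytest.raises(ValueError):
            per_cost_interaction(np.ones(20), ph)


class TestPartialCorrelation:
    def test_no_covariates_reduces_to_pearson(self, rng):
        x, y = rng.normal(size=(2, 60))
        r, p, n, k = partial_correlation(x, y)
        rr, pp = sps.pearsonr(x, y)
        assert (r, p) == (pytest.approx(rr), pytest.approx(pp))
        assert (n, k) == (60, 0)

    def test_variable_linear_in_covariates_is_degenerate(self, rng):
        c = rng.normal(size=(40, 2))
        y = 2 * c[:, 0] - c[:, 1] + 3
        with pytest.raises(ValueError, match="linear in the covariates"):
            partial_correlation(rng.normal(size=40), y, c)

    def test_recovers_known_partial_correlation(self, rng):
        """Trivariate normal with known partial correlation 0.5 at n=500."""
        rho = 0.5
        n = 500
        z = rng.normal(size=n)
        e1, e2 = rng.normal(size=(2, n))
        x = z + e1
        y = z + (rho / np.sqrt(1 - rho**2)) * e1 + e2 * 0  # construct directly
        # simpler construction: correlate residuals directly
        x = z + e1
        y = z + rho * e1 + np.sqrt(1 - rho**2) * e2
        r, _, _, _ = partial_correlation(x, y, z.reshape(-1, 1))
        assert r == pytest.approx(rho, abs=0.08)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        n = 45
        df = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("xyab"))
        df["y"] += 0.5 * df["x"] + 0.3 * df["a"]
        r, p, _, k = partial_correlation(
            df["x"].to_numpy(), df["y"].to_numpy(), df[["a", "b"]].to_numpy()
        )
        out = pg.partial_corr(df, x="x", y="y", covar=["a", "b"])
        assert r == pytest.approx(out["r"].item(), abs=1e-10)
        assert p == pytest.approx(out["p_val"].item(), abs=1e-10)
        assert k == 2

    def test_collinear_covariates_rejected(self, rng):
        c = rng.normal(size=40)
        cov = np.column_stack([c, 2 * c])
        with pytest.raises(ValueError, match="collinear"):
            partial_correlation(rng.normal(size=40), rng.normal(size=40), cov)


class TestCompareCorrelations:
    def test_equal_correlations_give_zero(self):
        z, p = compare_correlations(0.4, 30, 0.4, 50)
        assert z == 0.0 and p == 1.0

    def test_group_swap_negates_z(self):
        z1, p1 = compare_correlations(0.6, 25, 0.2, 40, k=3)
        z2, p2 = compare_correlations(0.2, 40, 0.6, 25, k=3)
        assert z1 == pytest.approx(-z2) and p1 == pytest.approx(p2)

    def test_reported_group_correlations_differ_significantly(self):
        """The exemplar group correlations (0.71 at n=21 vs 0.19 at n=44,
        3 covariates) differ at p < .05; closed form to 1e-10."""
        z, p = compare_correlations(0.71, 21, 0.19, 44, k=3)
        se = np.sqrt(1 / (21 - 3 - 3) + 1 / (44 - 3 - 3))
        z_hand = (np.arctanh(0.71) - np.arctanh(0.19)) / se
        assert z == pytest.approx(z_hand, abs=1e-10)
        assert p == pytest.approx(2 * sps.norm.sf(abs(z_hand)), abs=1e-10)
        assert p < 0.05

    def test_perfect_correlation_rejected(self):
        with pytest.raises(ValueError):
            compare_correlations(1.0, 30, 0.5, 30)

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_correlations(0.5, 6, 0.2, 40, k=3)


class TestAdjustPvalues:
    def test_hand_run_bh_step_up(self):
        p = np.array([0.001, 0.01, 0.02, 0.04, 0.2, 0.5, 0.9])
        flags = adjust_pvalues(p, "bh")
        assert flags.tolist() == [True, True, True, False, False, False, False]

    def test_all_ones_rejects_nothing(self):
        assert not adjust_pvalues(np.ones(7), "bh").any()
        assert not adjust_pvalues(np.ones(7), "bonferroni_threshold").any()

    def test_single_p_reduces_to_raw_threshold(self):
        assert adjust_pvalues([0.04], "bh").tolist() == [True]

    def test_bonferroni_threshold_is_0_0071_for_seven_costs(self):
        p = np.array([0.0070, 0.0072, 0.5, 0.5, 0.5, 0.5, 0.5])
        flags = adjust_pvalues(p, "bonferroni_threshold")
        assert flags.tolist() == [True, False, False, False, False, False, False]

    def test_bh_rejections_superset_of_bonferroni(self, rng):
        for _ in range(20):
            p = rng.uniform(size=7) ** 2
            bh = adjust_pvalues(p, "bh")
            bon = adjust_pvalues(p, "bonferroni_threshold")
            assert np.all(bh | ~bon)

    def test_matches_statsmodels_bh(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(20):
            p = rng.uniform(size=9)
            ours = adjust_pvalues(p, "bh")
            theirs = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            assert np.array_equal(ours, theirs)


class TestGroupCompare:
    def test_cohort_age_summaries(self):
        """Printed (mean, SD, n) age summaries give t = -1.92 to 2 dp."""
        t, p = pooled_t_from_summary(71.3, 5.7, 44, 74.4, 6.8, 21)
        assert t == pytest.approx(-1.92, abs=0.01)
        assert 0.05 < p < 0.07

    def test_identical_groups_give_zero_t(self):
        t, _ = pooled_t_from_summary(10, 2, 20, 10, 2, 25)
        assert t == 0.0

    def test_matches_scipy_on_raw_values(self, rng):
        ph = toy_pheno(rng, n=40)
        t, p = group_compare(ph, "memory")
        a = ph.loc[ph.abeta_positive == 0, "memory"]
        b = ph.loc[ph.abeta_positive == 1, "memory"]
        ref = sps.ttest_ind(a, b)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_categorical_uses_uncorrected_chi_square(self, rng):
        ph = toy_pheno(rng, n=60)
        chi2, p = group_compare(ph, "sex")
        tab = pd.crosstab(ph["sex"], ph["abeta_positive"]).to_numpy()
        ref = sps.chi2_contingency(tab, correction=False)
        assert chi2 == pytest.approx(ref.statistic)

    def test_zero_variance_is_error(self, rng):
        with pytest.raises(ValueError):
            pooled_t_from_summary(5, 0, 10, 5, 0, 12)


class TestGroupPartialCorrelations:
    def test_planted_group_specificity_recovered(self):
        cfg = SyntheticConfig(seed=1234)
        wide, ph, _ = generate_metric_table(cfg)
        out = group_partial_correlations(wide[0.25].to_numpy(), ph)
        pos = out.set_index("group").loc["abeta_pos"]
        neg = out.set_index("group").loc["abeta_neg"]
        assert pos["partial_r"] > neg["partial_r"]
        assert pos["n"] == 21 and neg["n"] == 44 and pos["k"] == 3

    def test_scan_has_one_row_per_cost_with_flags(self):
        cfg = SyntheticConfig(seed=2)
        wide, ph, _ = generate_metric_table(cfg)
        scan = interaction_scan(wide, ph)
        assert len(scan) == 7
        assert set(scan.columns) >= {"cost", "t", "p",
                                     "significant_unadjusted", "significant_adjusted"}
        # adjusted rejections are a subset of unadjusted ones
        assert np.all(scan["significant_unadjusted"] | ~scan["significant_adjusted"])


def test_pvalues_uniform_under_null():
    """Interaction p-values are U(0,1) under a null cohort (KS at alpha=.01)."""
    ps = []
    for i in range(300):
        cfg = SyntheticConfig(seed=90_000 + i, beta_interaction=0.0)
        wide, ph, _ = generate_metric_table(cfg)
        _, p = per_cost_interaction(wide[0.15].to_numpy(), ph)
        ps.append(p)
    assert sps.kstest(ps, "uniform").pvalue > 0.01
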