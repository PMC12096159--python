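"""Cohort statistics: LME ledger, rank tests, ANOVA, agreement."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
import statsmodels.api as sm

import vasodyn as v
from vasodyn.stats import (
    ModelSpec,
    anova2_sidak,
    cohen_kappa,
    icc_two_raters,
    mann_whitney,
    sidak_adjust,
    spearman,
)


class TestModelSpecParsing:
    def test_table_style_formulas(self):
        s = ModelSpec.from_formula(
            "log10(Vasomotion) ~ Abeta + Age × Genotype + (1|Mouse) + (1|FOV)"
        )
        assert s.transform == "log10"
        assert s.response == "vasomotion_peak"
        assert s.fixed_terms == ("abeta", "age", "genotype", "age_x_genotype")
        assert s.random_terms == (("mouse_id", "intercept"), ("fov_id", "intercept"))

    def test_uncorrelated_slope_notation(self):
        s = ModelSpec.from_formula("log10(Vasomotion) ~ Abeta + (1|Mouse) + (Age||FOV)")
        assert ("fov_id", "intercept_slope_age") in s.random_terms

    def test_interaction_requires_mains(self):
        with pytest.raises(ValueError, match="main"):
            ModelSpec(fixed_terms=("age_x_genotype",))


class TestFitLme:
    def test_degenerate_limit_matches_ols(self):
        # with all random SDs at zero the mixed model's fixed effects
        # coincide with ordinary least squares on the same design
        cfg = v.CohortSimConfig(
            n_mice_per_genotype=8, sd_mouse_intercept=0.0, sd_fov_intercept=0.0,
            sd_residual=0.05, beta_abeta=0.005, seed=21,
        )
        table, _ = v.gen_cohort(cfg)
        res = v.fit_lme(
            table, "log10(Vasomotion) ~ Abeta + Age * Genotype + (1|Mouse) + (1|FOV)"
        )
        tg = (table.genotype == "Tg").astype(float)
        X = sm.add_constant(
            pd.DataFrame(
                {"tg": tg, "abeta": table.abeta_coverage, "age": table.age,
                 "age_tg": table.age * tg}
            )
        )
        ols = sm.OLS(np.log10(table.vasomotion_peak), X).fit()
        got = res.fixed.estimate
        expect = {
            "Intercept": ols.params["const"],
            "C(genotype, Treatment('WT'))[T.Tg]": ols.params["tg"],
            "abeta_coverage": ols.params["abeta"],
            "age": ols.params["age"],
            "age:C(genotype, Treatment('WT'))[T.Tg]": ols.params["age_tg"],
        }
        for term, val in expect.items():
            assert got[term] == pytest.approx(val, abs=1e-6)

    def test_variance_components_recovered(self):
        # planted mouse-intercept SD 0.1 and residual 0.05 recovered
        # within 25 % when averaged over replicates
        mouse_vars, resid_vars = [], []
        for seed in range(40):
            cfg = v.CohortSimConfig(
                n_mice_per_genotype=25, n_fov_per_mouse=2,
                sd_mouse_intercept=0.1, sd_fov_intercept=0.0, sd_residual=0.05,
                seed=seed,
            )
            table, _ = v.gen_cohort(cfg)
            res = v.fit_lme(
                table, "log10(Vasomotion) ~ Abeta + Age * Genotype + (1|Mouse) + (1|FOV)"
            )
            mouse_vars.append(res.variance_components["mouse_id_intercept"])
            resid_vars.append(res.residual_variance)
        assert np.mean(mouse_vars) == pytest.approx(0.1**2, rel=0.25)
        assert np.mean(resid_vars) == pytest.approx(0.05**2, rel=0.25)

    def test_null_model_intercept_covers_zero(self):
        cfg = v.CohortSimConfig(
            intercept=0.0, beta_genotype=0.0, beta_age_x_genotype=0.0,
            sd_mouse_intercept=0.01, sd_fov_intercept=0.01, sd_residual=0.05,
            seed=5,
        )
        table, _ = v.gen_cohort(cfg)
        res = v.fit_lme(table, "log10(Vasomotion) ~ 1 + (1|Mouse) + (1|FOV)")
        row = res.fixed.loc["Intercept"]
        assert row.ci_low < 0.0 < row.ci_high

    def test_information_criteria_recomputable(self):
        table, _ = v.gen_cohort(v.CohortSimConfig(seed=7))
        res = v.fit_lme(table, "log10(Vasomotion) ~ Abeta + (1|Mouse) + (1|FOV)")
        assert res.aic == pytest.approx(-2 * res.log_likelihood + 2 * res.n_params, abs=1e-12)
        assert res.bic == pytest.approx(
            -2 * res.log_likelihood + res.n_params * np.log(res.n_obs), abs=1e-12
        )


class TestModelLedger:
    _FORMULAS = [
        "log10(Vasomotion) ~ 1 + (1|Mouse) + (1|FOV)",
        "log10(Vasomotion) ~ Abeta + (1|Mouse) + (1|FOV)",
        "log10(Vasomotion) ~ Abeta + Age + (1|Mouse) + (1|FOV)",
        "log10(Vasomotion) ~ Abeta + Age + Genotype + (1|Mouse) + (1|FOV)",
        "log10(Vasomotion) ~ Abeta + Age * Genotype + (1|Mouse) + (1|FOV)",
    ]

    def test_identical_specs_identical_rows(self):
        table, _ = v.gen_cohort(v.CohortSimConfig(seed=3))
        f = self._FORMULAS[1]
        ledger, _ = v.model_ledger(table, [f, f])
        a = ledger.drop(columns="selected").iloc[0]
        b = ledger.drop(columns="selected").iloc[1]
        assert a.equals(b)

    def test_loglik_non_decreasing_with_nested_fixed_terms(self):
        # under ML, adding a fixed term can never lower the log-likelihood
        table, _ = v.gen_cohort(v.CohortSimConfig(seed=13))
        ledger, _ = v.model_ledger(
            table, [self._FORMULAS[0], self._FORMULAS[1], self._FORMULAS[2],
                    self._FORMULAS[3], self._FORMULAS[4]]
        )
        ll = ledger.loglik.to_numpy()
        assert np.all(np.diff(ll) >= -1e-4)

    def test_mixed_responses_rejected(self):
        table, _ = v.gen_cohort(v.CohortSimConfig(seed=3))
        with pytest.raises(ValueError, match="share"):
            v.model_ledger(
                table,
                ["log10(Vasomotion) ~ 1 + (1|Mouse) + (1|FOV)",
                 "Vasomotion ~ 1 + (1|Mouse) + (1|FOV)"],
            )


def _brute_mw_p(x, y):
    """Test-local oracle: exact two-sided Mann-Whitney p by enumerating
    every assignment of group labels to the pooled sample."""
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    mean_u = n1 * (n - n1) / 2.0

    def u_of(idx):
        ranks = sps.rankdata(pooled)
        r1 = ranks[list(idx)].sum()
        return r1 - n1 * (n1 + 1) / 2.0

    obs = abs(u_of(range(n1)) - mean_u)
    hits = total = 0
    for comb in itertools.combinations(range(n), n1):
        total += 1
        if abs(u_of(comb) - mean_u) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_fully_separated_example(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.u == 0.0
        assert res.p == pytest.approx(0.1)  # 2 of 20 assignments as extreme
        assert res.method == "exact"

    def test_identical_samples(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.z == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_swap_flips_z_keeps_p(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 6), rng.normal(1, 1, 7)
        a, b = mann_whitney(x, y), mann_whitney(y, x)
        assert a.z == pytest.approx(-b.z, rel=1e-12)
        assert a.p == pytest.approx(b.p, rel=1e-12)

    def test_all_tied_flagged(self):
        res = mann_whitney([5, 5], [5, 5, 5])
        assert res.p == 1.0
        assert res.flag

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_p_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, rng.integers(3, 9)).astype(float)  # with ties
        y = rng.integers(0, 6, rng.integers(3, 9)).astype(float)
        res = mann_whitney(x, y)
        assert res.method == "exact"
        assert res.p == pytest.approx(_brute_mw_p(x, y), abs=1e-12)

    def test_large_sample_z_matches_scipy_normal_approx(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 20), rng.normal(0.8, 1, 25)
        res = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                               use_continuity=False)
        assert res.method == "normal"
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)


class TestSpearman:
    def test_monotone_limits(self):
        x = [1, 2, 3, 4, 5]
        assert spearman(x, [2, 4, 5, 7, 9]).rho == pytest.approx(1.0)
        assert spearman(x, [9, 7, 5, 4, 2]).rho == pytest.approx(-1.0)

    def test_hand_computed_rank_example(self):
        # ranks of x: 1,2,3,4; ranks of y: 2,1,4,3 -> rho = 0.6
        res = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.rho == pytest.approx(0.6)

    def test_constant_variable_flagged(self):
        res = spearman([1, 1, 1], [1, 2, 3])
        assert np.isnan(res.rho)
        assert res.flag

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_p_matches_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        x, y = rng.normal(size=n), rng.normal(size=n)
        res = spearman(x, y)
        assert res.method == "exact"
        # test-local oracle: permute y and count |rho| as or more extreme
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        hits = total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            total += 1
            if abs(r) >= obs - 1e-9:
                hits += 1
        assert res.p == pytest.approx(hits / total, abs=1e-12)

    def test_rho_matches_scipy_with_ties(self):
        rng = np.random.default_rng(9)
        x = rng.integers(0, 5, 30).astype(float)
        y = x + rng.normal(0, 2, 30)
        assert spearman(x, y).rho == pytest.approx(sps.spearmanr(x, y).statistic, rel=1e-9)


def _balanced_twoway_oracle(df):
    """Test-local two-way ANOVA by direct sums-of-squares decomposition
    (valid for balanced layouts, where Type I = Type II)."""
    grand = df.value.mean()
    n = len(df)
    a_means = df.groupby("A").value.mean()
    b_means = df.groupby("B").value.mean()
    cell_means = df.groupby(["A", "B"]).value.mean()
    n_a = df.groupby("A").size()
    n_b = df.groupby("B").size()
    n_cell = df.groupby(["A", "B"]).size()
    ss_a = float((n_a * (a_means - grand) ** 2).sum())
    ss_b = float((n_b * (b_means - grand) ** 2).sum())
    ss_cells = float((n_cell * (cell_means - grand) ** 2).sum())
    ss_ab = ss_cells - ss_a - ss_b
    resid = df.value - df.set_index(["A", "B"]).index.map(cell_means)
    ss_e = float((resid**2).sum())
    df_a, df_b = len(a_means) - 1, len(b_means) - 1
    df_ab = df_a * df_b
    df_e = n - len(cell_means)
    f_a = (ss_a / df_a) / (ss_e / df_e)
    f_b = (ss_b / df_b) / (ss_e / df_e)
    f_ab = (ss_ab / df_ab) / (ss_e / df_e)
    return f_a, f_b, f_ab


class TestAnova2Sidak:
    def _data(self, seed=0, interaction=0.0):
        rng = np.random.default_rng(seed)
        rows = []
        for a in ("WT", "Tg"):
            for b in (12, 18, 24):
                for _ in range(6):
                    val = rng.normal(0, 1) + (interaction if (a == "Tg" and b == 24) else 0)
                    rows.append({"A": a, "B": b, "value": val})
        return pd.DataFrame(rows)

    def test_f_statistics_match_direct_decomposition(self):
        df = self._data(seed=2, interaction=1.5)
        res = anova2_sidak(df.value, df.A, df.B)
        f_a, f_b, f_ab = _balanced_twoway_oracle(df)
        table = res.anova_table
        assert table.loc["C(A)", "F"] == pytest.approx(f_a, rel=1e-9)
        assert table.loc["C(B)", "F"] == pytest.approx(f_b, rel=1e-9)
        assert table.loc["C(A):C(B)", "F"] == pytest.approx(f_ab, rel=1e-9)

    def test_single_comparison_unadjusted(self):
        df = self._data(seed=3)
        res = anova2_sidak(df.value, df.A, df.B,
                           preselected=[(("WT", 24), ("Tg", 24))])
        row = res.pairwise.iloc[0]
        assert row.p_sidak == pytest.approx(row.p_raw, rel=1e-12)

    def test_sidak_formula(self):
        assert sidak_adjust(0.05, 3) == pytest.approx(0.142625, abs=1e-9)
        assert sidak_adjust(0.05, 1) == pytest.approx(0.05)

    def test_empty_cell_flags_and_drops_interaction(self):
        df = self._data(seed=4)
        df = df[~((df.A == "Tg") & (df.B == 24))]
        res = anova2_sidak(df.value, df.A, df.B)
        assert res.flag
        assert "C(A):C(B)" not in res.anova_table.index
        assert "C(A)" in res.anova_table.index

    def test_preselected_empty_cell_rejected(self):
        df = self._data(seed=5)
        with pytest.raises(ValueError, match="empty"):
            anova2_sidak(df.value, df.A, df.B,
                         preselected=[(("WT", 24), ("Tg", 99))])


class TestIcc:
    def test_perfect_agreement(self):
        s = np.column_stack([np.arange(6.0), np.arange(6.0)])
        assert icc_two_raters(s).value == pytest.approx(1.0)

    def test_anticorrelated_raters_negative(self):
        # mean-squares oracle on a 4-item table with symmetric spread
        s = np.array([[2.0, -2.0], [1.0, -1.0], [-1.0, 1.0], [-2.0, 2.0]])
        res = icc_two_raters(s)
        assert res.value < 0

    def test_matches_pingouin_icc2(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        item = rng.normal(0, 2, 12)
        s = np.column_stack([item + rng.normal(0, 1, 12), item + rng.normal(0, 1, 12) + 0.5])
        df = pd.DataFrame(
            {"targets": np.repeat(np.arange(12), 2),
             "raters": np.tile(["r1", "r2"], 12),
             "scores": s.ravel()}
        )
        ref = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="scores")
        icc2 = ref.loc[ref.Type.isin(["ICC2", "ICC(A,1)"]), "ICC"].iloc[0]
        assert icc_two_raters(s).value == pytest.approx(icc2, abs=1e-9)

    def test_independent_raters_near_zero_on_average(self):
        rng = np.random.default_rng(1)
        vals = [icc_two_raters(rng.normal(0, 1, (20, 2))).value for _ in range(1000)]
        assert abs(np.nanmean(vals)) < 0.05

    def test_degenerate_constant_table_flagged(self):
        s = np.full((4, 2), 3.0)
        res = icc_two_raters(s)
        assert np.isnan(res.value)
        assert res.flag


class TestKappa:
    def test_perfect_agreement(self):
        r = np.array([[0, 0], [1, 1], [2, 2], [1, 1]])
        assert cohen_kappa(r).value == pytest.approx(1.0)

    def test_hand_computed_half_agreement(self):
        # confusion matrix [[1,1],[1,1]]: p_o = 0.5, p_e = 0.5 -> kappa 0
        r = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        assert cohen_kappa(r).value == pytest.approx(0.0)

    def test_total_disagreement_balanced(self):
        r = np.array([[0, 1], [1, 0], [0, 1], [1, 0]])
        assert cohen_kappa(r).value == pytest.approx(-1.0)

    def test_matches_sklearn(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(2)
        a = rng.integers(0, 3, 50)
        b = np.where(rng.random(50) < 0.7, a, rng.integers(0, 3, 50))
        ours = cohen_kappa(np.column_stack([a, b])).value
        assert ours == pytest.approx(sk.cohen_kappa_score(a, b), abs=1e-12)

    def test_constant_raters_flagged_as_one(self):
        r = np.array([[1, 1], [1, 1]])
        res = cohen_kappa(r)
        assert res.value == 1.0
        assert res.flag
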