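import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

import fmrkit as fk
from fmrkit.errors import ConfigError, EstimationError

from conftest import make_summary


def _dosage_from_counts(n_aa, n_ab, n_bb, rng=None):
    col = np.concatenate([np.zeros(n_aa), np.ones(n_ab), np.full(n_bb, 2.0)])
    if rng is not None:
        rng.shuffle(col)
    return col


class TestHwe:
    def test_exact_proportions_give_p_one(self):
        assert fk.hwe_test(25, 50, 25) == pytest.approx(1.0)
        assert fk.hwe_test(81, 18, 1) == pytest.approx(1.0)

    def test_maximal_departure(self):
        # (50,0,50): chi-square = n = 100 under p=q=1/2
        p = fk.hwe_test(50, 0, 50)
        assert p == pytest.approx(stats.chi2.sf(100, 1), rel=1e-9)
        assert p < 1e-5

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ConfigError):
            fk.hwe_test(0, 0, 0)

    def test_monomorphic_returns_one(self):
        assert fk.hwe_test(100, 0, 0) == 1.0


class TestQc:
    def test_boundary_flags_are_exact(self):
        # columns engineered to straddle the MAF>0.01, missing<0.05,
        # HWE p>=1e-5 boundaries at n=100
        n = 100
        cols = {
            "mono": _dosage_from_counts(100, 0, 0),        # maf 0 -> fail maf
            "maf_at_bound": _dosage_from_counts(98, 2, 0),  # maf exactly 0.01 -> fail (> rule)
            "maf_above": _dosage_from_counts(96, 4, 0),     # maf 0.02 -> pass
            "hwe_fail": _dosage_from_counts(50, 0, 50),     # HWE p ~ 1.5e-23 -> fail
            "hwe_pass": _dosage_from_counts(25, 50, 25),    # HWE chi2 = 0 -> pass
        }
        miss_fail = _dosage_from_counts(47, 48, 0)
        miss_fail = np.concatenate([miss_fail, np.full(5, np.nan)])[:n]  # 5% missing -> fail
        miss_pass = _dosage_from_counts(48, 48, 0)
        miss_pass = np.concatenate([miss_pass, np.full(4, np.nan)])[:n]  # 4% -> pass
        cols["miss_at_bound"] = miss_fail
        cols["miss_below"] = miss_pass
        d = np.column_stack(list(cols.values()))
        report, filtered, kept = fk.qc_genotypes(d, list(cols))
        flags = report.table.set_index("snp")["passed"]
        assert not flags["mono"]
        assert not flags["maf_at_bound"]
        assert flags["maf_above"]
        assert not flags["hwe_fail"]
        assert flags["hwe_pass"]
        assert not flags["miss_at_bound"]
        assert flags["miss_below"]
        assert kept == ["maf_above", "hwe_pass", "miss_below"]
        assert filtered.shape == (n, 3)

    def test_fails_iff_any_flag_fails(self, small_cohort):
        report, _, _ = fk.qc_genotypes(small_cohort.dosages, small_cohort.snp_ids)
        t = report.table
        assert (t["passed"] == (t["pass_maf"] & t["pass_missing"] & t["pass_hwe"])).all()

    def test_empty_matrix_rejected(self):
        with pytest.raises(ConfigError):
            fk.qc_genotypes(np.empty((0, 0)), [])


class TestGwasScan:
    def test_perfect_fit_flagged(self):
        rng = np.random.default_rng(0)
        d = rng.binomial(2, 0.4, size=(200, 1)).astype(float)
        y = 2.0 * d[:, 0]
        out = fk.gwas_scan(d, y)
        assert out.loc[0, "beta"] == pytest.approx(2.0)
        assert out.loc[0, "flag"] == "perfect_fit"

    def test_constant_dosage_flagged_not_scanned(self):
        d = np.column_stack([np.ones(100), np.random.default_rng(1).binomial(2, 0.3, 100)])
        y = np.random.default_rng(2).normal(size=100)
        out = fk.gwas_scan(d, y, snp_ids=["const", "ok"])
        assert out.loc[0, "flag"] == "constant"
        assert np.isnan(out.loc[0, "beta"])
        assert out.loc[1, "flag"] == ""

    def test_matches_statsmodels_ols_with_covariates_and_missing(self):
        rng = np.random.default_rng(3)
        n, m = 400, 4
        d = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        d[rng.random((n, m)) < 0.1] = np.nan
        cov = rng.normal(size=(n, 2))
        y = 0.15 * np.nan_to_num(d[:, 0]) + cov @ [0.5, -0.2] + rng.normal(size=n)
        out = fk.gwas_scan(d, y, covariates=cov)
        for j in range(m):
            ok = ~np.isnan(d[:, j])
            x = sm.add_constant(np.column_stack([cov[ok], d[ok, j]]))
            ref = sm.OLS(y[ok], x).fit()
            assert out.loc[j, "beta"] == pytest.approx(ref.params[-1], rel=1e-9)
            assert out.loc[j, "se"] == pytest.approx(ref.bse[-1], rel=1e-9)
            assert out.loc[j, "pval"] == pytest.approx(ref.pvalues[-1], rel=1e-6)
            assert out.loc[j, "n"] == ok.sum()

    def test_univariate_beta_is_cov_over_var(self):
        rng = np.random.default_rng(4)
        d = rng.binomial(2, 0.4, size=(500, 1)).astype(float)
        y = 0.3 * d[:, 0] + rng.normal(size=500)
        out = fk.gwas_scan(d, y)
        expected = np.cov(d[:, 0], y)[0, 1] / np.var(d[:, 0], ddof=1)
        assert out.loc[0, "beta"] == pytest.approx(expected, rel=1e-10)

    def test_simulated_effect_recovered(self, big_cohort):
        c = big_cohort
        out = fk.gwas_scan(c.dosages, c.glu, c.covariates[["age", "sex"]].to_numpy(),
                           c.snp_ids)
        truth = {s.id: s.beta_glu for s in c.truth.config.snp_spec}
        row = out.loc[out["snp"] == "rs_glu0000"].iloc[0]
        assert abs(row["beta"] - truth["rs_glu0000"]) < 3 * row["se"]


class TestLdPrune:
    def test_duplicate_column_keeps_most_significant(self):
        rng = np.random.default_rng(5)
        base = rng.binomial(2, 0.3, 3000).astype(float)
        other = rng.binomial(2, 0.3, 3000).astype(float)
        d = np.column_stack([base, base, other])
        stats_df = make_summary(["a", "b", "c"], [1e-9, 1e-10, 1e-4])
        kept = fk.ld_prune(stats_df, d, ["a", "b", "c"], r2_max=0.01)
        assert "b" in kept and "a" not in kept and "c" in kept

    def test_independent_snps_all_retained(self, small_cohort):
        ids = small_cohort.snp_ids
        stats_df = make_summary(ids, np.linspace(1e-9, 1e-3, len(ids)))
        kept = fk.ld_prune(stats_df, small_cohort.dosages, ids, r2_max=0.01)
        assert set(kept) == set(ids)

    def test_pvalue_tie_broken_by_snp_id(self):
        rng = np.random.default_rng(6)
        base = rng.binomial(2, 0.3, 300).astype(float)
        d = np.column_stack([base, base])
        stats_df = make_summary(["z_late", "a_early"], [1e-8, 1e-8])
        kept = fk.ld_prune(stats_df, d, ["z_late", "a_early"], r2_max=0.01)
        assert kept == ["a_early"]

    def test_order_independence(self):
        rng = np.random.default_rng(7)
        d = rng.binomial(2, 0.3, size=(400, 6)).astype(float)
        d[:, 3] = d[:, 0]  # one LD pair
        ids = [f"s{j}" for j in range(6)]
        stats_df = make_summary(ids, [1e-9, 1e-8, 1e-7, 1e-6, 1e-5, 1e-4])
        kept1 = fk.ld_prune(stats_df, d, ids)
        shuffled = stats_df.sample(frac=1, random_state=0).reset_index(drop=True)
        kept2 = fk.ld_prune(shuffled, d, ids)
        assert kept1 == kept2


class TestSelectInstruments:
    def test_threshold_straddle_exact(self):
        exp = make_summary(
            ["keep1", "gw_edge", "gw_fail", "screen_fail", "screen_edge"],
            [1e-9, 5e-8, 1e-7, 1e-9, 1e-9],
        )
        screens = {
            "bmi": make_summary(
                ["keep1", "screen_fail", "screen_edge"], [0.5, 1e-8, 1e-7]
            )
        }
        iv = fk.select_instruments(exp, screens, exposure="glu")
        # 5e-8 is not < 5e-8; screen p exactly 1e-7 is not < 1e-7 so passes
        assert iv.snp_ids == ["keep1", "screen_edge"]
        reasons = iv.exclusions.set_index("snp")["reason"]
        assert reasons["gw_edge"] == "genome_wide"
        assert reasons["gw_fail"] == "genome_wide"
        assert reasons["screen_fail"] == "confounder_screen:bmi"

    def test_snp_absent_from_screen_passes(self):
        exp = make_summary(["a"], [1e-9])
        iv = fk.select_instruments(exp, {"bmi": make_summary(["other"], [1e-9])})
        assert iv.snp_ids == ["a"]

    def test_empty_selection_raises(self):
        exp = make_summary(["a"], [0.5])
        with pytest.raises(EstimationError):
            fk.select_instruments(exp)

    def test_idempotent_on_own_output(self):
        exp = make_summary(["a", "b", "c"], [1e-9, 1e-10, 1e-12])
        iv = fk.select_instruments(exp, {})
        iv2 = fk.select_instruments(iv.table, {})
        pd.testing.assert_frame_equal(iv.table, iv2.table)
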