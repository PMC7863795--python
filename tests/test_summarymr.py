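import math

import numpy as np
import pandas as pd
import pytest

import fmrkit as fk
from fmrkit.errors import ConfigError, EstimationError
from fmrkit.summarymr import HarmonizedData

from conftest import make_summary


def _stats(snps, betas, ses, effect, other, pvals=None):
    from scipy import stats as sps

    betas = np.asarray(betas, float)
    ses = np.asarray(ses, float)
    if pvals is None:
        pvals = 2 * sps.norm.sf(np.abs(betas) / ses)
    df = make_summary(snps, pvals, betas=betas, ses=ses)
    df["effect_allele"] = effect
    df["other_allele"] = other
    return df


def _harm(bx, by, sy=0.01, sx=0.001, snps=None, bx2=None, sy2=None):
    bx = np.asarray(bx, float)
    tab = pd.DataFrame(
        {
            "snp": snps or [f"s{i}" for i in range(len(bx))],
            "beta_x": bx,
            "se_x": np.full(len(bx), sx) if np.isscalar(sx) else sx,
            "beta_y": np.asarray(by, float),
            "se_y": np.full(len(bx), sy) if np.isscalar(sy) else sy,
        }
    )
    if bx2 is not None:
        tab["beta_x2"] = np.asarray(bx2, float)
        tab["se_x2"] = 0.001
    return HarmonizedData(tab)


class TestHarmonize:
    def test_identical_coding_unchanged(self):
        e = _stats(["a"], [0.1], [0.01], ["A"], ["G"])
        o = _stats(["a"], [0.02], [0.01], ["A"], ["G"])
        h = fk.harmonize(e, o)
        assert h.table.loc[0, "beta_y"] == pytest.approx(0.02)

    def test_swapped_alleles_negate_outcome(self):
        e = _stats(["a"], [0.1], [0.01], ["A"], ["G"])
        o = _stats(["a"], [0.02], [0.01], ["G"], ["A"])
        h = fk.harmonize(e, o)
        assert h.table.loc[0, "beta_y"] == pytest.approx(-0.02)

    def test_complement_strand_swapped_negates(self):
        e = _stats(["a"], [0.1], [0.01], ["A"], ["G"])
        o = _stats(["a"], [0.02], [0.01], ["C"], ["T"])  # complement of swapped
        h = fk.harmonize(e, o)
        assert h.table.loc[0, "beta_y"] == pytest.approx(-0.02)

    def test_ambiguous_snp_dropped_with_reason(self):
        e = _stats(["a", "b"], [0.1, 0.1], [0.01, 0.01], ["A", "A"], ["T", "G"])
        o = _stats(["a", "b"], [0.02, 0.02], [0.01, 0.01], ["A", "A"], ["T", "G"])
        h = fk.harmonize(e, o)
        assert h.table["snp"].tolist() == ["b"]
        assert h.dropped.set_index("snp").loc["a", "reason"] == "strand-ambiguous"

    def test_allele_mismatch_dropped(self):
        e = _stats(["a"], [0.1], [0.01], ["A"], ["G"])
        o = _stats(["a"], [0.02], [0.01], ["A"], ["C"])
        h = fk.harmonize(e, o)
        assert len(h) == 0 and h.dropped.loc[0, "reason"] == "allele_mismatch"

    def test_zero_overlap_rejected(self):
        e = _stats(["a"], [0.1], [0.01], ["A"], ["G"])
        o = _stats(["b"], [0.02], [0.01], ["A"], ["G"])
        with pytest.raises(EstimationError):
            fk.harmonize(e, o)


class TestWaldRatioAndIvw:
    def test_wald_examples(self):
        assert fk.wald_ratio(0.1, 0.01, 0.0, 0.01) == (0.0, pytest.approx(0.1))
        est, _ = fk.wald_ratio(0.1, 0.01, 0.02, 0.01)
        assert est == pytest.approx(0.2)
        c = 3.7
        assert fk.wald_ratio(c * 0.1, 0.01, c * 0.02, 0.01)[0] == pytest.approx(0.2)
        with pytest.raises(EstimationError):
            fk.wald_ratio(0.0, 0.01, 0.02, 0.01)

    def test_ivw_hand_formula(self):
        h = _harm([0.1, 0.2], [0.02, 0.05], sy=0.01)
        res = fk.ivw(h)
        # weights (100, 400) scaled by 1/se^2: estimate (0.2*100+0.25*400)/500
        assert res.estimate == pytest.approx(0.24, rel=1e-12)
        assert res.se == pytest.approx(1 / math.sqrt(500) * 0.01 / 0.01, rel=1e-12)
        assert res.se == pytest.approx(1 / math.sqrt((0.1**2 + 0.2**2) / 0.01**2), rel=1e-12)

    def test_single_snp_reduces_to_wald_ratio(self):
        h = _harm([0.13], [0.031], sy=0.012)
        res = fk.ivw(h)
        w_est, w_se = fk.wald_ratio(0.13, 0.0, 0.031, 0.012)
        assert res.estimate == pytest.approx(w_est, rel=1e-12)
        assert res.se == pytest.approx(w_se, rel=1e-12)

    def test_consistency_simulation(self):
        rng = np.random.default_rng(20)
        m, theta = 200, 0.25
        bx = rng.uniform(0.05, 0.15, m)
        by = theta * bx + 0.01 * rng.standard_normal(m)
        res = fk.ivw(_harm(bx, by, sy=0.01))
        assert abs(res.estimate - theta) < 3 * res.se


class TestEgger:
    def test_noiseless_proportional_data(self):
        bx = np.linspace(0.05, 0.2, 10)
        res = fk.mr_egger(_harm(bx, 0.3 * bx))
        assert res.estimate == pytest.approx(0.3, rel=1e-9)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_constant_pleiotropy_shifts_intercept_only(self):
        bx = np.linspace(0.05, 0.2, 10)
        res = fk.mr_egger(_harm(bx, 0.3 * bx + 0.01))
        assert res.intercept == pytest.approx(0.01, rel=1e-9)
        assert res.estimate == pytest.approx(0.3, rel=1e-9)

    def test_orientation_flip_invariance(self):
        rng = np.random.default_rng(21)
        bx = rng.uniform(0.05, 0.2, 20)
        by = 0.3 * bx + 0.01 * rng.standard_normal(20)
        flip = np.ones(20)
        flip[::3] = -1.0
        r1 = fk.mr_egger(_harm(bx, by))
        r2 = fk.mr_egger(_harm(bx * flip, by * flip))
        assert r1.estimate == pytest.approx(r2.estimate, rel=1e-12)
        assert r1.intercept == pytest.approx(r2.intercept, rel=1e-12)

    def test_slope_equals_ivw_when_intercept_constrained(self):
        rng = np.random.default_rng(22)
        bx = rng.uniform(0.05, 0.2, 30)
        by = 0.2 * bx + 0.01 * rng.standard_normal(30)
        h = _harm(bx, by)
        import statsmodels.api as sm

        constrained = sm.WLS(by, bx[:, None], weights=1 / 0.01**2 * np.ones(30)).fit()
        assert fk.ivw(h).estimate == pytest.approx(float(constrained.params[0]), rel=1e-10)

    def test_too_few_snps_rejected(self):
        with pytest.raises(EstimationError):
            fk.mr_egger(_harm([0.1, 0.2], [0.02, 0.04]))


class TestPresso:
    def _data(self, rng, m=60, theta=0.2, inflate=None):
        bx = rng.uniform(0.05, 0.15, m)
        by = theta * bx + 0.02 * rng.standard_normal(m)
        if inflate is not None:
            by[inflate] = 10 * theta * bx[inflate]
        return _harm(bx, by, sy=0.02, sx=0.005)

    def test_deterministic_given_seed(self):
        h = self._data(np.random.default_rng(23))
        a = fk.mr_presso(h, n_sim=200, seed=9)
        b = fk.mr_presso(h, n_sim=200, seed=9)
        assert a[0] == b[0] and a[1] == b[1]
        assert a[2].estimate == b[2].estimate

    def test_planted_outlier_flagged_and_corrected_estimate_identity(self):
        rng = np.random.default_rng(24)
        h = self._data(rng, inflate=7)
        global_p, outliers, corrected = fk.mr_presso(h, n_sim=500, seed=1)
        assert "s7" in outliers
        assert global_p <= 0.05
        # corrected estimate is exactly IVW on the non-outlying SNPs
        kept = HarmonizedData(h.table.loc[~h.table["snp"].isin(outliers)].reset_index(drop=True))
        assert corrected.estimate == pytest.approx(fk.ivw(kept).estimate, rel=1e-12)

    def test_outlier_removal_reduces_bias_in_expectation(self):
        err_naive, err_corr = [], []
        for s in range(20):
            rng = np.random.default_rng(1000 + s)
            h = self._data(rng, inflate=3)
            _, _, corrected = fk.mr_presso(h, n_sim=300, seed=s)
            err_naive.append(abs(fk.ivw(h).estimate - 0.2))
            err_corr.append(abs(corrected.estimate - 0.2))
        assert np.mean(err_corr) < np.mean(err_naive)

    def test_null_rarely_flags(self):
        rng = np.random.default_rng(25)
        n_out = sum(
            len(fk.mr_presso(self._data(rng), n_sim=300, seed=s)[1]) for s in range(10)
        )
        assert n_out <= 3  # ~0.003 expected per SNP-set under Bonferroni

    def test_too_few_snps_rejected(self):
        with pytest.raises(EstimationError):
            fk.mr_presso(_harm([0.1, 0.2, 0.3], [0.02, 0.04, 0.06]))


class TestMvmr:
    def test_noiseless_two_exposure_recovery(self):
        rng = np.random.default_rng(26)
        bx1 = rng.uniform(0.05, 0.15, 20)
        bx2 = rng.uniform(-0.1, 0.1, 20)
        by = 0.3 * bx1 - 0.2 * bx2
        res = fk.mvmr(_harm(bx1, by, bx2=bx2))
        assert res["exposure1"].estimate == pytest.approx(0.3, rel=1e-9)
        assert res["exposure2"].estimate == pytest.approx(-0.2, rel=1e-9)

    def test_null_second_exposure_reduces_to_ivw(self):
        rng = np.random.default_rng(27)
        bx = rng.uniform(0.05, 0.15, 15)
        by = 0.25 * bx + 0.01 * rng.standard_normal(15)
        res = fk.mvmr(_harm(bx, by, bx2=np.zeros(15)))
        ivw_res = fk.ivw(_harm(bx, by))
        assert res["exposure1"].estimate == pytest.approx(ivw_res.estimate, rel=1e-10)
        assert res["exposure2"].estimate == 0.0

    def test_collinear_exposures_rejected(self):
        bx = np.linspace(0.05, 0.2, 10)
        with pytest.raises(EstimationError):
            fk.mvmr(_harm(bx, 0.3 * bx, bx2=2 * bx))

    def test_confounded_exposure_corrected(self):
        # exposure2 (e.g. BMI) affects the outcome; SNPs act on both
        rng = np.random.default_rng(28)
        m = 100
        bx2 = rng.uniform(0.0, 0.1, m)
        bx1 = 0.5 * bx2 + rng.uniform(0.05, 0.15, m)
        theta1, theta2 = 0.2, 0.4
        by = theta1 * bx1 + theta2 * bx2 + 0.005 * rng.standard_normal(m)
        uni = fk.ivw(_harm(bx1, by, sy=0.005))
        multi = fk.mvmr(_harm(bx1, by, sy=0.005, bx2=bx2))
        assert abs(multi["exposure1"].estimate - theta1) < abs(uni.estimate - theta1)


class TestContinuousGrsMr:
    def test_weak_instrument_warning(self):
        rng = np.random.default_rng(29)
        n = 2000
        grs = rng.normal(size=n)
        pheno = rng.normal(size=n)
        y = rng.binomial(1, 0.3, n)
        res = fk.continuous_grs_mr(grs, pheno, y)
        assert any("weak instrument" in w for w in res.warnings)

    def test_grs_rescaling_invariance(self):
        rng = np.random.default_rng(30)
        n = 3000
        grs = rng.normal(size=n)
        pheno = 0.5 * grs + rng.normal(size=n)
        y = rng.binomial(1, 0.5, n)
        a = fk.continuous_grs_mr(grs, pheno, y)
        b = fk.continuous_grs_mr(10 * grs, pheno, y)
        assert a.estimate == pytest.approx(b.estimate, rel=1e-9)

    def test_recovers_one_sd_effect(self):
        rng = np.random.default_rng(31)
        n = 30_000
        grs = rng.normal(size=n)
        pheno = 0.4 * grs + rng.normal(size=n) * 0.6
        sd = pheno.std()
        theta = math.log(1.3) / sd  # per-unit effect giving 1-SD OR 1.3
        from scipy.special import expit

        y = (rng.random(n) < expit(-1.0 + theta * pheno)).astype(int)
        res = fk.continuous_grs_mr(grs, pheno, y)
        assert abs(res.estimate - math.log(1.3)) < 3 * res.se
        assert res.diagnostics["stage1_f"] > 10
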