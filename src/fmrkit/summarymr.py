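"""Summary-statistics Mendelian randomization estimators.

Implements the estimators used for instrument cleaning and verification:
allele harmonization, Wald ratios, fixed-effect inverse-variance weighting
(IVW), MR-Egger with its directional-pleiotropy intercept test, the
MR-PRESSO residual-sum-of-squares outlier search, multivariable MR, and the
individual-level continuous-GRS two-step MR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ConfigError, EstimationError

__all__ = [
    "HarmonizedData",
    "MRResult",
    "harmonize",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "mr_presso",
    "mvmr",
    "continuous_grs_mr",
]

Z95 = stats.norm.ppf(0.975)
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class HarmonizedData:
    """Per-SNP exposure/outcome effects aligned to a common effect allele.

    `table` columns: snp, beta_x, se_x, beta_y, se_y (+ beta_x2, se_x2 for
    MVMR). `dropped` records SNPs excluded during harmonization and why.
    """

    table: pd.DataFrame
    dropped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp", "reason"])
    )

    def __len__(self) -> int:
        return len(self.table)

    def arrays(self):
        t = self.table
        return (
            t["beta_x"].to_numpy(float),
            t["se_x"].to_numpy(float),
            t["beta_y"].to_numpy(float),
            t["se_y"].to_numpy(float),
        )


@dataclass
class MRResult:
    """Estimator output on the log-odds (or outcome-beta) scale."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_snps: int | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    global_p: float | None = None
    outliers: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()
    diagnostics: dict = field(default_factory=dict)

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.estimate)


def _mk_result(method, est, se, p=None, **kw) -> MRResult:
    if p is None:
        p = float(2 * stats.norm.sf(abs(est) / se)) if se > 0 else 0.0
    return MRResult(
        method, float(est), float(se), float(est - Z95 * se), float(est + Z95 * se),
        float(p), **kw
    )


def _is_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame) -> HarmonizedData:
    """Join exposure/outcome summary stats on SNP id and align alleles.

    When the outcome's effect/other alleles are swapped relative to the
    exposure (directly or on the complementary strand), the outcome beta is
    negated. Strand-ambiguous (A/T, C/G) SNPs and unresolvable allele pairs
    are dropped with a logged reason.
    """
    merged = exposure.merge(outcome, on="snp", suffixes=("_x", "_y"))
    if merged.empty:
        raise EstimationError("no overlapping SNPs between exposure and outcome")
    rows, dropped = [], []
    for _, r in merged.iterrows():
        e1, o1 = str(r["effect_allele_x"]).upper(), str(r["other_allele_x"]).upper()
        e2, o2 = str(r["effect_allele_y"]).upper(), str(r["other_allele_y"]).upper()
        if _is_ambiguous(e1, o1):
            dropped.append({"snp": r["snp"], "reason": "strand-ambiguous"})
            continue
        ce2, co2 = _COMPLEMENT.get(e2, "?"), _COMPLEMENT.get(o2, "?")
        if (e2, o2) == (e1, o1) or (ce2, co2) == (e1, o1):
            flip = 1.0
        elif (e2, o2) == (o1, e1) or (ce2, co2) == (o1, e1):
            flip = -1.0
        else:
            dropped.append({"snp": r["snp"], "reason": "allele_mismatch"})
            continue
        rows.append(
            {
                "snp": r["snp"],
                "beta_x": float(r["beta_x"]),
                "se_x": float(r["se_x"]),
                "beta_y": flip * float(r["beta_y"]),
                "se_y": float(r["se_y"]),
            }
        )
    return HarmonizedData(
        pd.DataFrame(rows, columns=["snp", "beta_x", "se_x", "beta_y", "se_y"]),
        pd.DataFrame(dropped, columns=["snp", "reason"]),
    )


def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float) -> tuple[float, float]:
    """Single-SNP ratio estimate beta_y/beta_x with first-order SE |se_y/beta_x|."""
    if beta_x == 0:
        raise EstimationError("Wald ratio undefined for beta_x = 0")
    return beta_y / beta_x, abs(se_y / beta_x)


def ivw(data: HarmonizedData) -> MRResult:
    """Fixed-effect inverse-variance-weighted estimate.

    Weighted mean of per-SNP Wald ratios with first-order weights
    w_j = beta_x_j^2 / se_y_j^2; se = 1/sqrt(sum w).
    """
    if len(data) < 1:
        raise EstimationError("IVW needs at least one SNP")
    bx, _, by, sy = data.arrays()
    if np.any(bx == 0):
        raise EstimationError("IVW undefined with beta_x = 0 SNPs; filter them first")
    w = bx**2 / sy**2
    est = float((w * (by / bx)).sum() / w.sum())
    se = float(1.0 / math.sqrt(w.sum()))
    return _mk_result("ivw", est, se, n_snps=len(data))


def mr_egger(data: HarmonizedData) -> MRResult:
    """MR-Egger: WLS of beta_y on beta_x with intercept, weights 1/se_y^2.

    SNPs are first oriented so every exposure beta is non-negative (flipping
    negates both betas). The slope is the causal estimate; a non-zero
    intercept indicates directional horizontal pleiotropy. Inference uses
    the multiplicative overdispersion scale estimated by the regression
    (t-based p-values).
    """
    if len(data) < 3:
        raise EstimationError("MR-Egger needs at least 3 SNPs")
    bx, _, by, sy = data.arrays()
    flip = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * flip, by * flip
    x = sm.add_constant(bx)
    res = sm.WLS(by, x, weights=1.0 / sy**2).fit()
    slope, slope_se = float(res.params[1]), float(res.bse[1])
    return _mk_result(
        "mr_egger",
        slope,
        slope_se,
        p=float(res.pvalues[1]),
        n_snps=len(bx),
        intercept=float(res.params[0]),
        intercept_se=float(res.bse[0]),
        intercept_p=float(res.pvalues[0]),
    )


def _loo_ivw(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes, vectorized; works on 1-D or (sims, m) arrays."""
    num = (w * bx * by).sum(axis=-1, keepdims=True) - w * bx * by
    den = (w * bx * bx).sum(axis=-1, keepdims=True) - w * bx * bx
    return num / den


def mr_presso(
    data: HarmonizedData,
    n_sim: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, list[str], MRResult]:
    """MR-PRESSO global test and outlier search.

    Observed RSS sums w_j (beta_y_j - theta_(-j) beta_x_j)^2 over SNPs with
    w_j = 1/se_y_j^2 and theta_(-j) the leave-one-out IVW slope. The null
    distribution comes from `n_sim` parametric draws beta_x* ~ N(beta_x,
    se_x), beta_y* ~ N(theta_(-j) beta_x, se_y), each resimulated dataset
    contributing its own leave-one-out RSS. The global p is the fraction of
    simulated RSS >= observed; per-SNP outlier p-values are the empirical
    tail fractions of each SNP's contribution, Bonferroni-multiplied by m.
    Returns (global_p, outlier ids, IVW on the non-outlying SNPs).
    """
    m = len(data)
    if m < 4:
        raise EstimationError("MR-PRESSO needs at least 4 SNPs")
    if n_sim < 100:
        raise ConfigError("n_sim must be >= 100")
    bx, sx, by, sy = data.arrays()
    w = 1.0 / sy**2
    theta_loo = _loo_ivw(bx, by, w)
    obs_contrib = w * (by - theta_loo * bx) ** 2
    obs_rss = float(obs_contrib.sum())

    rng = np.random.default_rng(seed)
    bx_s = rng.normal(bx, sx, size=(n_sim, m))
    by_s = rng.normal(theta_loo * bx, sy, size=(n_sim, m))
    theta_loo_s = _loo_ivw(bx_s, by_s, w)
    sim_contrib = w * (by_s - theta_loo_s * bx_s) ** 2
    sim_rss = sim_contrib.sum(axis=1)
    global_p = float((sim_rss >= obs_rss).mean())

    p_snp = (sim_contrib >= obs_contrib).mean(axis=0) * m  # Bonferroni
    snps = data.table["snp"].to_numpy()
    outliers = [str(s) for s, p in zip(snps, p_snp) if p < alpha]
    if len(outliers) == m:
        raise EstimationError("all SNPs flagged as outliers; no corrected estimate")
    kept = HarmonizedData(data.table.loc[~data.table["snp"].isin(outliers)].reset_index(drop=True))
    corrected = ivw(kept)
    corrected = MRResult(
        **{**corrected.__dict__, "method": "ivw_presso_corrected",
           "global_p": global_p, "outliers": tuple(outliers)}
    )
    return global_p, outliers, corrected


def mvmr(data: HarmonizedData) -> dict[str, MRResult]:
    """Multivariable MR: WLS of beta_y on (beta_x1, beta_x2) through the
    origin with weights 1/se_y^2; per-exposure estimate/SE/p.

    A second exposure that is identically zero reduces to univariate IVW for
    the first (its own coefficient is reported as zero with infinite SE).
    """
    t = data.table
    if "beta_x2" not in t.columns:
        raise ConfigError("MVMR needs beta_x2/se_x2 columns in the harmonized table")
    if len(t) < 3:
        raise EstimationError("MVMR needs at least 3 SNPs")
    x1 = t["beta_x"].to_numpy(float)
    x2 = t["beta_x2"].to_numpy(float)
    by = t["beta_y"].to_numpy(float)
    sy = t["se_y"].to_numpy(float)
    w = 1.0 / sy**2
    x = np.column_stack([x1, x2])
    active = [j for j in range(2) if np.any(x[:, j] != 0)]
    if len(active) == 2 and np.linalg.matrix_rank(x) < 2:
        raise EstimationError("exposure betas are collinear; MVMR not identifiable")
    xa = x[:, active]
    sw = np.sqrt(w)
    coef_a, *_ = np.linalg.lstsq(xa * sw[:, None], by * sw, rcond=None)
    cov_a = np.linalg.pinv(xa.T @ (xa * w[:, None]))
    out: dict[str, MRResult] = {}
    names = ["exposure1", "exposure2"]
    for j, name in enumerate(names):
        if j in active:
            i = active.index(j)
            est, se = float(coef_a[i]), float(math.sqrt(cov_a[i, i]))
            out[name] = _mk_result("mvmr", est, se, n_snps=len(t))
        else:
            out[name] = MRResult("mvmr", 0.0, math.inf, -math.inf, math.inf, 1.0,
                                 n_snps=len(t), warnings=("exposure betas all zero",))
    return out


def continuous_grs_mr(
    grs,
    phenotype,
    outcome,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> MRResult:
    """Two-step MR with a continuous GRS instrument, individual-level data.

    Stage 1: OLS of the phenotype on the GRS (+ covariates); stage 2:
    logistic regression of the outcome on the stage-1 fitted exposure
    (+ covariates). The effect is reported per 1 SD of the phenotype; the SE
    is the first-order two-stage (stage-2 Wald) approximation. A stage-1
    F below 10 is recorded as a weak-instrument warning.
    """
    s = np.asarray(getattr(grs, "scores", grs), dtype=float)
    y = np.asarray(outcome, dtype=float)
    pheno = np.asarray(phenotype, dtype=float)
    n = len(s)
    if not (len(y) == len(pheno) == n):
        raise ConfigError("grs/phenotype/outcome lengths differ")
    if covariates is not None:
        cmat = np.asarray(covariates, dtype=float)
        x1 = np.column_stack([np.ones(n), s, cmat])
    else:
        cmat = None
        x1 = np.column_stack([np.ones(n), s])
    stage1 = sm.OLS(pheno, x1).fit()
    fstat = float((stage1.params[1] / stage1.bse[1]) ** 2)
    warnings = () if fstat >= 10 else (f"weak instrument: stage-1 F = {fstat:.2f}",)
    xhat = stage1.fittedvalues
    x2 = np.column_stack([np.ones(n), xhat]) if cmat is None else np.column_stack(
        [np.ones(n), xhat, cmat]
    )
    stage2 = sm.GLM(y, x2, family=sm.families.Binomial()).fit()
    sd = float(np.std(pheno))
    est = float(stage2.params[1]) * sd
    se = float(stage2.bse[1]) * sd
    return _mk_result(
        "two_step_grs", est, se,
        p=float(stage2.pvalues[1]),
        warnings=warnings,
        diagnostics={"stage1_f": fstat, "phenotype_sd": sd},
    )
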