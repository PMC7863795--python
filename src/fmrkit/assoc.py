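"""Per-SNP QC, association scan, LD pruning, and instrument selection.

Summary statistics travel as a pandas DataFrame in the dialect
``snp, effect_allele, other_allele, eaf, beta, se, pval, n`` (the
SummaryStats layout shared with :mod:`fmrkit.summarymr` and the TSV I/O).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, EstimationError

__all__ = [
    "SUMMARY_COLUMNS",
    "QCReport",
    "InstrumentSet",
    "hwe_test",
    "qc_genotypes",
    "gwas_scan",
    "ld_prune",
    "select_instruments",
    "validate_summary_stats",
]

SUMMARY_COLUMNS = ["snp", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"]

# default QC and selection thresholds
DEFAULT_MAF_MIN = 0.01
DEFAULT_MISSING_MAX = 0.05
DEFAULT_HWE_ALPHA = 1e-5
DEFAULT_P_GW = 5e-8
DEFAULT_P_PLEIO = 1e-7
DEFAULT_R2_MAX = 0.01


def validate_summary_stats(df: pd.DataFrame, check_pz: bool = False) -> None:
    """Check the SummaryStats contract; raise ConfigError on violation.

    With `check_pz`, also require the p-value to be consistent with beta/se
    under the two-sided normal approximation to within 10% on the z scale
    (skipped for p below the double-precision floor).
    """
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"summary stats missing columns: {missing}")
    if df["snp"].duplicated().any():
        raise ConfigError("duplicate SNP ids in summary stats")
    if (df["se"] <= 0).any():
        raise ConfigError("se must be > 0")
    if ((df["pval"] <= 0) | (df["pval"] > 1)).any():
        raise ConfigError("pval must be in (0, 1]")
    if check_pz:
        ok = (df["pval"] > 1e-280) & (df["pval"] < 1.0)
        z_stated = stats.norm.isf(df.loc[ok, "pval"] / 2.0)
        z_implied = (df.loc[ok, "beta"].abs() / df.loc[ok, "se"]).to_numpy()
        bad = np.abs(z_stated - z_implied) > 0.10 * np.maximum(z_implied, 1e-12)
        if bad.any():
            raise ConfigError(
                f"pval inconsistent with beta/se for SNPs: "
                f"{df.loc[ok].loc[bad, 'snp'].tolist()[:5]}"
            )


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Hardy-Weinberg 1-df chi-square goodness-of-fit p-value.

    Expected proportions p^2, 2pq, q^2 with the allele frequency estimated
    from the counts themselves.
    """
    counts = np.array([n_aa, n_ab, n_bb], dtype=float)
    if (counts < 0).any():
        raise ConfigError("genotype counts must be non-negative")
    n = counts.sum()
    if n < 1:
        raise ConfigError("at least one genotype observation required")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0  # monomorphic: expected == observed
    expected = n * np.array([p**2, 2 * p * q, q**2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


@dataclass
class QCReport:
    """Per-SNP QC metrics and pass/fail flags; a SNP fails iff any flag fails."""

    table: pd.DataFrame  # snp, maf, missing_rate, hwe_p, pass_maf, pass_missing, pass_hwe, passed

    @property
    def passed_snps(self) -> list[str]:
        return self.table.loc[self.table["passed"], "snp"].tolist()


def qc_genotypes(
    dosages: np.ndarray,
    snp_ids,
    maf_min: float = DEFAULT_MAF_MIN,
    missing_max: float = DEFAULT_MISSING_MAX,
    hwe_alpha: float = DEFAULT_HWE_ALPHA,
) -> tuple[QCReport, np.ndarray, list[str]]:
    """Filter SNPs on MAF > maf_min, missing < missing_max, HWE p >= hwe_alpha.

    Returns (report, filtered dosage matrix, retained SNP ids).
    """
    dosages = np.asarray(dosages, dtype=float)
    if dosages.size == 0:
        raise ConfigError("empty dosage matrix")
    snp_ids = list(snp_ids)
    n, m = dosages.shape
    rows = []
    for j in range(m):
        col = dosages[:, j]
        obs = col[~np.isnan(col)]
        missing_rate = 1.0 - len(obs) / n
        if len(obs) == 0:
            maf, hwe_p = 0.0, 1.0
        else:
            af = float(obs.mean() / 2.0)
            maf = min(af, 1.0 - af)
            g = np.round(obs).astype(int)
            hwe_p = hwe_test(int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))
        pass_maf = maf > maf_min
        pass_missing = missing_rate < missing_max
        pass_hwe = hwe_p >= hwe_alpha
        rows.append(
            {
                "snp": snp_ids[j],
                "maf": maf,
                "missing_rate": missing_rate,
                "hwe_p": hwe_p,
                "pass_maf": pass_maf,
                "pass_missing": pass_missing,
                "pass_hwe": pass_hwe,
                "passed": pass_maf and pass_missing and pass_hwe,
            }
        )
    table = pd.DataFrame(rows)
    keep = table["passed"].to_numpy()
    return QCReport(table), dosages[:, keep], [s for s, k in zip(snp_ids, keep) if k]


def _scan_complete(dosages, y, covars):
    """OLS scan with no missing dosages, via Frisch-Waugh residualization.

    Identical (beta, se, p) to per-SNP full OLS of y on [1, covars, dosage];
    the residual df accounts for all fitted columns.
    """
    n, m = dosages.shape
    q, _ = np.linalg.qr(covars)
    ry = y - q @ (q.T @ y)
    rd = dosages - q @ (q.T @ dosages)
    sxx = np.einsum("ij,ij->j", rd, rd)
    sxy = rd.T @ ry
    syy = float(ry @ ry)
    df = n - covars.shape[1] - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = np.maximum(syy - beta**2 * sxx, 0.0)
        se = np.sqrt(rss / df / sxx)
        tstat = beta / se
    pval = 2 * stats.t.sf(np.abs(tstat), df)
    return beta, se, pval, np.full(m, n), sxx


def gwas_scan(
    dosages: np.ndarray,
    phenotype: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    snp_ids=None,
    effect_alleles=None,
    other_alleles=None,
) -> pd.DataFrame:
    """Per-SNP OLS of phenotype on dosage plus covariates.

    Individuals with a missing dosage are dropped for that SNP only
    (complete-case per SNP). Constant dosage columns are flagged
    ``constant`` and a perfect fit (zero residual) is flagged
    ``perfect_fit``; both get NaN/0 accordingly rather than aborting the
    scan. Returns a SummaryStats frame with an extra ``flag`` column.
    """
    dosages = np.asarray(dosages, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    n, m = dosages.shape
    if len(y) != n:
        raise ConfigError("phenotype length does not match dosage matrix")
    if snp_ids is None:
        snp_ids = [f"snp{j}" for j in range(m)]
    snp_ids = list(snp_ids)
    effect_alleles = list(effect_alleles) if effect_alleles is not None else ["A"] * m
    other_alleles = list(other_alleles) if other_alleles is not None else ["G"] * m
    if covariates is None:
        covars = np.ones((n, 1))
    else:
        cmat = np.asarray(covariates, dtype=float)
        covars = np.column_stack([np.ones(n), cmat])

    has_missing = bool(np.isnan(dosages).any())
    if not has_missing:
        beta, se, pval, nobs, sxx = _scan_complete(dosages, y, covars)
    else:
        beta = np.empty(m)
        se = np.empty(m)
        pval = np.empty(m)
        nobs = np.empty(m, dtype=int)
        sxx = np.empty(m)
        for j in range(m):
            col = dosages[:, j]
            ok = ~np.isnan(col)
            bj, sj, pj, nj, xj = _scan_complete(
                col[ok][:, None], y[ok], covars[ok]
            )
            beta[j], se[j], pval[j], nobs[j], sxx[j] = bj[0], sj[0], pj[0], nj[0], xj[0]

    with np.errstate(invalid="ignore"):
        eaf = np.nanmean(dosages, axis=0) / 2.0
    flag = np.where(sxx <= 1e-12, "constant", "")
    flag = np.where((flag == "") & (se == 0.0), "perfect_fit", flag)
    beta = np.where(flag == "constant", np.nan, beta)
    se = np.where(flag == "constant", np.nan, se)
    pval = np.where(flag == "constant", np.nan, pval)
    return pd.DataFrame(
        {
            "snp": snp_ids,
            "effect_allele": effect_alleles,
            "other_allele": other_alleles,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": nobs,
            "flag": flag,
        }
    )


def ld_prune(
    stats_df: pd.DataFrame,
    dosages: np.ndarray,
    snp_ids,
    r2_max: float = DEFAULT_R2_MAX,
) -> list[str]:
    """Greedy LD pruning: visit SNPs by ascending p-value (ties broken by
    lexicographic SNP id), keep a SNP iff its squared dosage correlation with
    every already-kept SNP is below `r2_max`.

    The ordering rule makes the output independent of input row order.
    """
    snp_ids = list(snp_ids)
    idx_of = {s: j for j, s in enumerate(snp_ids)}
    order = stats_df[["snp", "pval"]].dropna().sort_values(["pval", "snp"], kind="mergesort")
    dmat = pd.DataFrame(np.asarray(dosages, dtype=float), columns=range(len(snp_ids)))
    kept: list[str] = []
    kept_idx: list[int] = []
    corr_cache = dmat.corr() if dmat.isna().any().any() else None
    if corr_cache is None:
        x = dmat.to_numpy()
        xc = x - x.mean(axis=0)
        norms = np.sqrt((xc**2).sum(axis=0))
        for snp in order["snp"]:
            j = idx_of[snp]
            if norms[j] == 0:
                continue
            ok = True
            for k in kept_idx:
                r = float(xc[:, j] @ xc[:, k] / (norms[j] * norms[k])) if norms[k] else 0.0
                if r * r >= r2_max:
                    ok = False
                    break
            if ok:
                kept.append(snp)
                kept_idx.append(j)
    else:
        for snp in order["snp"]:
            j = idx_of[snp]
            if all((corr_cache.iloc[j, k] ** 2) < r2_max for k in kept_idx):
                kept.append(snp)
                kept_idx.append(j)
    return kept


@dataclass
class InstrumentSet:
    """Instruments for one exposure: retained SNPs with weights, plus the
    provenance of every exclusion (which filter removed which SNP)."""

    exposure: str
    table: pd.DataFrame  # SummaryStats columns for retained SNPs
    exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp", "reason"])
    )

    def __post_init__(self) -> None:
        if self.table["snp"].duplicated().any():
            raise ConfigError("duplicate SNP ids in instrument set")

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp"].tolist()

    def drop(self, snp_ids, reason: str) -> "InstrumentSet":
        """New InstrumentSet without `snp_ids`, recording `reason`."""
        snp_ids = set(snp_ids)
        extra = pd.DataFrame({"snp": sorted(snp_ids), "reason": reason})
        return InstrumentSet(
            exposure=self.exposure,
            table=self.table.loc[~self.table["snp"].isin(snp_ids)].reset_index(drop=True),
            exclusions=pd.concat([self.exclusions, extra], ignore_index=True),
        )


def select_instruments(
    stats_exposure: pd.DataFrame,
    stats_other: dict[str, pd.DataFrame] | None = None,
    p_gw: float = DEFAULT_P_GW,
    p_pleio: float = DEFAULT_P_PLEIO,
    exposure: str = "exposure",
) -> InstrumentSet:
    """Select instruments: exposure p < p_gw, every screen p >= p_pleio.

    `stats_other` maps screen names (e.g. other trait, BMI) to SummaryStats
    frames; a SNP absent from a screening table passes that screen (no
    evidence of association). Exclusions are recorded per SNP as
    ``genome_wide`` or ``confounder_screen:<name>``.
    """
    stats_other = stats_other or {}
    exclusions = []
    keep_mask = []
    screen_p = {
        name: tab.set_index("snp")["pval"] for name, tab in stats_other.items()
    }
    for _, row in stats_exposure.iterrows():
        snp = row["snp"]
        if not (row["pval"] < p_gw):
            exclusions.append({"snp": snp, "reason": "genome_wide"})
            keep_mask.append(False)
            continue
        failed = None
        for name, pser in screen_p.items():
            p = pser.get(snp, np.nan)
            if np.isfinite(p) and p < p_pleio:
                failed = name
                break
        if failed is not None:
            exclusions.append({"snp": snp, "reason": f"confounder_screen:{failed}"})
            keep_mask.append(False)
        else:
            keep_mask.append(True)
    table = stats_exposure.loc[keep_mask].reset_index(drop=True)
    if table.empty:
        raise EstimationError(
            "no instruments retained; review the p_gw/p_pleio thresholds or the scan"
        )
    return InstrumentSet(
        exposure=exposure,
        table=table,
        exclusions=pd.DataFrame(exclusions, columns=["snp", "reason"]),
    )
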