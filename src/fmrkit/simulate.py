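"""Synthetic individual-level cohort generator.

Emulates the statistical structure of a biobank-style factorial MR analysis:
independent biallelic SNPs with trait-specific, shared, and directly
pleiotropic effects; non-fasting glucose (GLU, mmol/L) and log triglyceride
(log TG, log mmol/L) built from genetic, covariate, confounder, and residual
components; the TyG insulin-resistance index; and a binary outcome from a
logistic model with configurable causal effects of GLU and log TG.

Every stochastic draw is driven by a single integer seed through
`numpy.random.SeedSequence` spawning, so a cohort is bit-reproducible. The
hidden confounder and all generative parameters are retained in a
`TruthRecord` so that downstream analyses can be tested for parameter
recovery and for robustness to confounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .errors import ConfigError, DomainError

__all__ = [
    "SnpSpec",
    "SimConfig",
    "Cohort",
    "TruthRecord",
    "make_snp_spec",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_outcome",
    "simulate_cohort",
    "compute_tyg",
    "GLU_MGDL_PER_MMOL",
    "TG_MGDL_PER_MMOL",
]

# Standard clinical unit conversions (mmol/L -> mg/dl).
GLU_MGDL_PER_MMOL = 18.0182
TG_MGDL_PER_MMOL = 88.57

#: covariate name -> (theoretical mean, theoretical variance). Marginals:
#: age ~ U(40,69) years, sex ~ Bern(0.5), bmi ~ N(27,4) kg/m2,
#: smoke ~ Bern(0.1), fasting_time ~ U(0,24) h, ldl ~ N(3.5,0.8) mmol/L.
COVARIATE_MOMENTS: dict[str, tuple[float, float]] = {
    "age": (54.5, 29.0**2 / 12.0),
    "sex": (0.5, 0.25),
    "bmi": (27.0, 16.0),
    "smoke": (0.1, 0.09),
    "fasting_time": (12.0, 24.0**2 / 12.0),
    "ldl": (3.5, 0.64),
}

#: covariate -> (effect on GLU mmol/L, on log TG, on outcome log-odds),
#: applied to mean-centred covariate values. Plausible defaults; configurable.
DEFAULT_COVARIATE_EFFECTS: dict[str, tuple[float, float, float]] = {
    "age": (0.005, 0.002, 0.02),
    "sex": (0.05, 0.05, 0.30),
    "bmi": (0.010, 0.010, 0.05),
    "smoke": (0.0, 0.05, 0.30),
    "fasting_time": (-0.010, -0.005, 0.0),
    "ldl": (0.0, 0.05, 0.15),
}


@dataclass(frozen=True)
class SnpSpec:
    """One simulated biallelic SNP.

    `beta_glu` / `beta_tg` are per-effect-allele effects on GLU (mmol/L) and
    log TG; `beta_direct` is a per-allele direct effect on the outcome
    log-odds (horizontal pleiotropy, violating the exclusion restriction).
    """

    id: str
    maf: float
    beta_glu: float = 0.0
    beta_tg: float = 0.0
    beta_direct: float = 0.0
    effect_allele: str = "A"
    other_allele: str = "G"

    def __post_init__(self) -> None:
        if not (0.0 < self.maf < 1.0):
            raise ConfigError(f"SNP {self.id}: MAF must be in (0,1), got {self.maf}")


def _as_effects(
    effects: Mapping[str, tuple[float, float, float]],
) -> dict[str, tuple[float, float, float]]:
    for name in effects:
        if name not in COVARIATE_MOMENTS:
            raise ConfigError(f"unknown covariate in covariate_effects: {name!r}")
    return dict(effects)


@dataclass
class SimConfig:
    """Full parameterization of a synthetic cohort.

    Residual SDs may be given directly; when left as None they are calibrated
    by variance decomposition so that the total phenotype SDs equal
    `sd_glu_total` / `sd_tg_total` (defaults 0.62 mmol/L and 0.50 log mmol/L,
    the 1-SD scaling units of the analysis).
    """

    n_individuals: int
    snp_spec: Sequence[SnpSpec]
    confounder_effect_glu: float = 0.25
    confounder_effect_tg: float = 0.25
    confounder_effect_outcome: float = 0.30
    covariate_effects: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    resid_sd_glu: float | None = None
    resid_sd_tg: float | None = None
    sd_glu_total: float = 0.62
    sd_tg_total: float = 0.50
    glu_mean: float = 5.0
    log_tg_mean: float = 0.0
    theta_glu: float = math.log(1.20) / 0.62
    theta_tg: float = math.log(1.32) / 0.50
    baseline_logodds: float | None = None
    target_prevalence: float = 0.20
    genotype_missing_rate: float = 0.0
    ld_blocks: Sequence[tuple[int, int, float]] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ConfigError("n_individuals must be >= 2")
        if not self.snp_spec:
            raise ConfigError("snp_spec must contain at least one SNP")
        ids = [s.id for s in self.snp_spec]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate SNP ids in snp_spec")
        if not (0.0 <= self.genotype_missing_rate < 1.0):
            raise ConfigError("genotype_missing_rate must be in [0,1)")
        self.covariate_effects = _as_effects(self.covariate_effects)
        for sd, nm in ((self.resid_sd_glu, "resid_sd_glu"), (self.resid_sd_tg, "resid_sd_tg")):
            if sd is not None and sd <= 0:
                raise ConfigError(f"{nm} must be > 0")
        for start, stop, r in self.ld_blocks:
            if not (0 <= start < stop <= len(self.snp_spec)):
                raise ConfigError(f"ld block ({start},{stop}) out of range")
            if not (0.0 <= r < 1.0):
                raise ConfigError(f"ld block correlation must be in [0,1), got {r}")

    # -- variance bookkeeping -------------------------------------------------

    def genetic_variance(self) -> tuple[float, float]:
        """(var of genetic GLU component, var of genetic log-TG component)."""
        vg = sum(2 * s.maf * (1 - s.maf) * s.beta_glu**2 for s in self.snp_spec)
        vt = sum(2 * s.maf * (1 - s.maf) * s.beta_tg**2 for s in self.snp_spec)
        return vg, vt

    def covariate_variance(self) -> tuple[float, float]:
        vg = sum(
            e[0] ** 2 * COVARIATE_MOMENTS[c][1] for c, e in self.covariate_effects.items()
        )
        vt = sum(
            e[1] ** 2 * COVARIATE_MOMENTS[c][1] for c, e in self.covariate_effects.items()
        )
        return vg, vt

    def resolved_resid_sds(self) -> tuple[float, float]:
        """Residual SDs, calibrating against the total-SD targets when unset."""
        out = []
        gvar = self.genetic_variance()
        cvar = self.covariate_variance()
        conf = (self.confounder_effect_glu**2, self.confounder_effect_tg**2)
        for i, (given, total) in enumerate(
            ((self.resid_sd_glu, self.sd_glu_total), (self.resid_sd_tg, self.sd_tg_total))
        ):
            if given is not None:
                out.append(given)
                continue
            resid_var = total**2 - gvar[i] - cvar[i] - conf[i]
            if resid_var <= 0:
                raise ConfigError(
                    "total SD target too small for the configured genetic/covariate/"
                    f"confounder variance (component {['glu', 'tg'][i]})"
                )
            out.append(math.sqrt(resid_var))
        return out[0], out[1]


def make_snp_spec(
    n_glu: int = 60,
    n_tg: int = 150,
    n_shared: int = 0,
    n_pleiotropic: int = 0,
    beta_direct: float = 0.05,
    n_individuals: int = 50_000,
    chi2_per_snp: float = 80.0,
    maf_range: tuple[float, float] = (0.10, 0.50),
    sd_glu: float = 0.62,
    sd_tg: float = 0.50,
    seed: int = 0,
) -> list[SnpSpec]:
    """Build a SNP panel whose per-SNP effects are detectable at scale.

    Each trait SNP's effect size is set so that its expected association
    chi-square at `n_individuals` equals `chi2_per_snp` (default 80, z≈8.9),
    i.e. instruments are genome-wide significant at the simulated sample size
    just as the study's instruments were at biobank scale. `n_shared` of the
    GLU SNPs additionally affect log TG; `n_pleiotropic` of the TG SNPs get a
    direct outcome effect `beta_direct` (exclusion-restriction violators).
    """
    rng = np.random.default_rng(seed)
    r2 = chi2_per_snp / n_individuals
    spec: list[SnpSpec] = []

    def beta_for(maf: float, sd: float) -> float:
        return math.sqrt(r2 * sd**2 / (2 * maf * (1 - maf)))

    for i in range(n_glu):
        maf = float(rng.uniform(*maf_range))
        b_tg = beta_for(maf, sd_tg) if i < n_shared else 0.0
        spec.append(SnpSpec(f"rs_glu{i:04d}", maf, beta_glu=beta_for(maf, sd_glu), beta_tg=b_tg))
    for i in range(n_tg):
        maf = float(rng.uniform(*maf_range))
        b_dir = beta_direct if i < n_pleiotropic else 0.0
        spec.append(
            SnpSpec(f"rs_tg{i:04d}", maf, beta_tg=beta_for(maf, sd_tg), beta_direct=b_dir)
        )
    return spec


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def simulate_genotypes(
    n: int,
    snp_spec: Sequence[SnpSpec],
    missing_rate: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
    ld_blocks: Sequence[tuple[int, int, float]] = (),
) -> np.ndarray:
    """Draw an n x m dosage matrix; entries in {0,1,2} or NaN (missing).

    Independent Binomial(2, maf) per SNP by default. For each `(start, stop,
    r)` LD block the two allele copies are drawn from a Gaussian copula with
    equicorrelation `r` between SNPs, which preserves the marginal MAF while
    inducing within-block dosage correlation (used only to exercise LD
    pruning).
    """
    if n < 2:
        raise ConfigError("n must be >= 2")
    if not (0.0 <= missing_rate < 1.0):
        raise ConfigError("missing_rate must be in [0,1)")
    mafs = np.array([s.maf for s in snp_spec], dtype=float)  # validates via SnpSpec
    rng = np.random.default_rng(seed)
    m = len(mafs)
    dosages = rng.binomial(2, mafs, size=(n, m)).astype(float)
    from scipy.stats import norm

    for start, stop, r in ld_blocks:
        width = stop - start
        thr = norm.ppf(mafs[start:stop])
        block = np.zeros((n, width))
        for _copy in range(2):
            z_common = rng.standard_normal(n)[:, None]
            z = math.sqrt(r) * z_common + math.sqrt(1.0 - r) * rng.standard_normal((n, width))
            block += (z < thr).astype(float)
        dosages[:, start:stop] = block
    if missing_rate > 0:
        mask = rng.random((n, m)) < missing_rate
        dosages[mask] = np.nan
    return dosages


def _sample_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": rng.uniform(40.0, 69.0, n),
            "sex": rng.binomial(1, 0.5, n).astype(float),
            "bmi": rng.normal(27.0, 4.0, n),
            "smoke": rng.binomial(1, 0.1, n).astype(float),
            "fasting_time": rng.uniform(0.0, 24.0, n),
            "ldl": rng.normal(3.5, 0.8, n),
        }
    )


def _centered_cov_term(covariates: pd.DataFrame, effects, index: int) -> np.ndarray:
    term = np.zeros(len(covariates))
    for name, eff in effects.items():
        term += eff[index] * (covariates[name].to_numpy() - COVARIATE_MOMENTS[name][0])
    return term


def simulate_phenotypes(
    dosages: np.ndarray,
    config: SimConfig,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, np.ndarray]:
    """Simulate (glu, log_tg, covariates, confounder) given dosages.

    glu_i = glu_mean + sum_j beta_glu_j d_ij - E[genetic] + covariate terms
    (mean-centred) + confounder term + Normal(0, resid_sd_glu); log TG is
    analogous. Missing dosages contribute 0 to the genetic sum.
    """
    dosages = np.asarray(dosages, dtype=float)
    if dosages.ndim != 2 or dosages.shape[1] != len(config.snp_spec):
        raise ConfigError(
            f"dosage matrix has {dosages.shape[-1] if dosages.ndim == 2 else '?'} SNPs, "
            f"snp_spec has {len(config.snp_spec)}"
        )
    n = dosages.shape[0]
    if seed is None:
        seed = np.random.SeedSequence([config.seed, 1])
    rng = np.random.default_rng(seed)
    covariates = _sample_covariates(rng, n)
    confounder = rng.standard_normal(n)
    d0 = np.nan_to_num(dosages, nan=0.0)
    b_glu = np.array([s.beta_glu for s in config.snp_spec])
    b_tg = np.array([s.beta_tg for s in config.snp_spec])
    mafs = np.array([s.maf for s in config.snp_spec])
    resid_glu, resid_tg = config.resolved_resid_sds()
    glu = (
        config.glu_mean
        + d0 @ b_glu
        - float(2 * mafs @ b_glu)
        + _centered_cov_term(covariates, config.covariate_effects, 0)
        + config.confounder_effect_glu * confounder
        + rng.normal(0.0, resid_glu, n)
    )
    log_tg = (
        config.log_tg_mean
        + d0 @ b_tg
        - float(2 * mafs @ b_tg)
        + _centered_cov_term(covariates, config.covariate_effects, 1)
        + config.confounder_effect_tg * confounder
        + rng.normal(0.0, resid_tg, n)
    )
    return glu, log_tg, covariates, confounder


def compute_tyg(glu_mmol, tg_mmol):
    """TyG index: ln( TG[mg/dl] x GLU[mg/dl] / 2 ), inputs in mmol/L.

    Accepts scalars or arrays; raises DomainError on non-positive input.
    """
    glu_mmol = np.asarray(glu_mmol, dtype=float)
    tg_mmol = np.asarray(tg_mmol, dtype=float)
    if np.any(glu_mmol <= 0) or np.any(tg_mmol <= 0):
        raise DomainError("glucose and triglyceride must be positive for the TyG index")
    out = np.log(tg_mmol * TG_MGDL_PER_MMOL * glu_mmol * GLU_MGDL_PER_MMOL / 2.0)
    return float(out) if out.ndim == 0 else out


def _solve_baseline(lp_rest: np.ndarray, target: float) -> float:
    """Intercept b such that mean(expit(b + lp_rest)) == target."""
    if not (0.0 < target < 1.0):
        raise ConfigError("target_prevalence must be in (0,1)")

    def f(b):
        return float(np.mean(expit(b + lp_rest))) - target

    return float(brentq(f, -40.0, 40.0, xtol=1e-10))


def simulate_outcome(
    glu: np.ndarray,
    log_tg: np.ndarray,
    covariates: pd.DataFrame,
    confounder: np.ndarray,
    dosages: np.ndarray,
    config: SimConfig,
    seed: int | np.random.SeedSequence | None = None,
    return_baseline: bool = False,
):
    """Bernoulli outcome from the logistic structural model.

    Y_i ~ Bern(expit(baseline + theta_glu*glu + theta_tg*log_tg + covariate
    terms + confounder term + sum_j beta_direct_j*d_ij)). When
    `config.baseline_logodds` is None the baseline is solved so the expected
    prevalence equals `config.target_prevalence`.
    """
    n = len(glu)
    if not (len(log_tg) == len(confounder) == len(covariates) == dosages.shape[0] == n):
        raise ConfigError("phenotype/covariate/dosage lengths differ")
    if seed is None:
        seed = np.random.SeedSequence([config.seed, 2])
    rng = np.random.default_rng(seed)
    b_dir = np.array([s.beta_direct for s in config.snp_spec])
    lp = (
        config.theta_glu * np.asarray(glu)
        + config.theta_tg * np.asarray(log_tg)
        + _centered_cov_term(covariates, config.covariate_effects, 2)
        + config.confounder_effect_outcome * np.asarray(confounder)
        + np.nan_to_num(np.asarray(dosages, float), nan=0.0) @ b_dir
    )
    baseline = (
        config.baseline_logodds
        if config.baseline_logodds is not None
        else _solve_baseline(lp, config.target_prevalence)
    )
    outcome = (rng.random(n) < expit(baseline + lp)).astype(int)
    if return_baseline:
        return outcome, baseline
    return outcome


# ---------------------------------------------------------------------------
# cohort container
# ---------------------------------------------------------------------------


@dataclass
class TruthRecord:
    """Generative ground truth: the config plus realized quantities.

    Round-trips losslessly through the flat key-value text serialization in
    `fmrkit.io.write_truth` / `read_truth`.
    """

    config: SimConfig
    realized_eaf: dict[str, float]
    realized_sd_glu: float
    realized_sd_tg: float
    baseline_logodds: float
    pleiotropic_snps: tuple[str, ...]

    @property
    def true_or_1sd_glu(self) -> float:
        return math.exp(self.config.theta_glu * self.config.sd_glu_total)

    @property
    def true_or_1sd_tg(self) -> float:
        return math.exp(self.config.theta_tg * self.config.sd_tg_total)


@dataclass
class Cohort:
    """Individual-level cohort: dosages, phenotypes, covariates, outcome."""

    dosages: np.ndarray
    snp_ids: list[str]
    effect_alleles: list[str]
    other_alleles: list[str]
    glu: np.ndarray
    log_tg: np.ndarray
    tyg: np.ndarray
    covariates: pd.DataFrame
    confounder: np.ndarray
    outcome: np.ndarray
    truth: TruthRecord

    @property
    def n(self) -> int:
        return len(self.glu)

    def phenotype_frame(self) -> pd.DataFrame:
        """Phenotypes + covariates + outcome as one table (truth excluded)."""
        df = pd.DataFrame(
            {
                "iid": [f"id{i:07d}" for i in range(self.n)],
                "glu": self.glu,
                "log_tg": self.log_tg,
                "tyg": self.tyg,
            }
        )
        for c in self.covariates.columns:
            df[c] = self.covariates[c].to_numpy()
        df["outcome"] = self.outcome
        return df


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate a full cohort (genotypes, phenotypes, TyG, outcome, truth)."""
    streams = np.random.SeedSequence(config.seed).spawn(3)
    dosages = simulate_genotypes(
        config.n_individuals,
        config.snp_spec,
        config.genotype_missing_rate,
        seed=streams[0],
        ld_blocks=config.ld_blocks,
    )
    glu, log_tg, covariates, confounder = simulate_phenotypes(dosages, config, seed=streams[1])
    tyg = compute_tyg(glu, np.exp(log_tg))
    outcome, baseline = simulate_outcome(
        glu, log_tg, covariates, confounder, dosages, config, seed=streams[2], return_baseline=True
    )
    with np.errstate(invalid="ignore"):
        eaf = np.nanmean(dosages, axis=0) / 2.0
    truth = TruthRecord(
        config=replace(config),
        realized_eaf={s.id: float(f) for s, f in zip(config.snp_spec, eaf)},
        realized_sd_glu=float(np.std(glu)),
        realized_sd_tg=float(np.std(log_tg)),
        baseline_logodds=float(baseline),
        pleiotropic_snps=tuple(s.id for s in config.snp_spec if s.beta_direct != 0.0),
    )
    return Cohort(
        dosages=dosages,
        snp_ids=[s.id for s in config.snp_spec],
        effect_alleles=[s.effect_allele for s in config.snp_spec],
        other_alleles=[s.other_allele for s in config.snp_spec],
        glu=glu,
        log_tg=log_tg,
        tyg=tyg,
        covariates=covariates,
        confounder=confounder,
        outcome=outcome,
        truth=truth,
    )
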