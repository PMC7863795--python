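"""End-to-end orchestration of the factorial MR workflow on a cohort.

simulate -> QC -> association scans -> LD pruning -> instrument selection
(incl. MR-PRESSO cleaning) -> GRS -> factorial designs -> adjusted subgroup
effects + crude differences -> 1-SD scaling -> dose-response meta-regression
-> continuous two-step MR -> MR-Egger diagnostics, plus the observational
analogue (phenotype splits in place of GRS splits).

Every stage logs record counts in and out; with an output directory the run
writes each intermediate as TSV together with the echoed config and a run
log, so a run is reproducible from its directory alone.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml
from scipy import stats as sps

from . import io as fio
from .assoc import (
    DEFAULT_HWE_ALPHA,
    DEFAULT_MAF_MIN,
    DEFAULT_MISSING_MAX,
    DEFAULT_P_GW,
    DEFAULT_P_PLEIO,
    DEFAULT_R2_MAX,
    InstrumentSet,
    gwas_scan,
    ld_prune,
    qc_genotypes,
    select_instruments,
)
from .errors import ConfigError, FmrError
from .factorial import (
    assign_factorial,
    assign_median_split,
    assign_quantile_groups,
    cochran_q,
    crude_difference,
    estimate_subgroup_effects,
    scale_effect,
)
from .doseresponse import fit_bivariate_metareg, fit_univariate_metareg, predict_joint_effect
from .grs import build_grs, variance_explained
from .simulate import Cohort, SimConfig, SnpSpec, make_snp_spec, simulate_cohort
from .summarymr import HarmonizedData, continuous_grs_mr, mr_egger, mr_presso

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "default_config"]

Z95 = sps.norm.ppf(0.975)

_KNOWN_DESIGNS = ("2x2", "2x4_glu_binary", "2x4_tg_binary", "KxK", "tyg_quantiles")


@dataclass
class PipelineConfig:
    """All analysis choices; defaults follow the study's stated values."""

    sim: SimConfig
    covariates: tuple[str, ...] = ("age", "sex", "bmi", "smoke", "fasting_time", "ldl")
    scan_covariates: tuple[str, ...] = ("age", "sex")
    maf_min: float = DEFAULT_MAF_MIN
    missing_max: float = DEFAULT_MISSING_MAX
    hwe_alpha: float = DEFAULT_HWE_ALPHA
    p_gw: float = DEFAULT_P_GW
    p_pleio: float = DEFAULT_P_PLEIO
    r2_max: float = DEFAULT_R2_MAX
    sd_target_glu: float = 0.62
    sd_target_tg: float = 0.50
    designs: tuple[str, ...] = _KNOWN_DESIGNS
    kxk: int = 3
    tyg_k: int = 4
    weighted: bool = True
    presso: bool = True
    presso_nsim: int = 1000
    presso_alpha: float = 0.05
    observational: bool = True
    continuous_mr: bool = True
    egger: bool = True
    include_tyg: bool = True

    def __post_init__(self) -> None:
        for d in self.designs:
            if d not in _KNOWN_DESIGNS:
                raise ConfigError(f"unknown design {d!r}; known: {_KNOWN_DESIGNS}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "sim" not in raw:
            raise ConfigError("pipeline config must contain a 'sim' section")
        simraw = raw.pop("sim")
        sim_fields = set(SimConfig.__dataclass_fields__)
        unknown = set(simraw) - sim_fields
        if unknown:
            raise ConfigError(f"unknown sim config keys: {sorted(unknown)}")
        if "snp_spec" in simraw:
            simraw["snp_spec"] = [SnpSpec(**s) for s in simraw["snp_spec"]]
        else:
            simraw["snp_spec"] = make_snp_spec(
                n_individuals=simraw.get("n_individuals", 50_000)
            )
        if "covariate_effects" in simraw:
            simraw["covariate_effects"] = {
                k: tuple(v) for k, v in simraw["covariate_effects"].items()
            }
        sim = SimConfig(**simraw)
        pipe_fields = set(cls.__dataclass_fields__) - {"sim"}
        unknown = set(raw) - pipe_fields
        if unknown:
            raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
        for key in ("covariates", "scan_covariates", "designs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(sim=sim, **raw)

    def to_yaml(self) -> str:
        d = asdict(self)
        d["sim"]["snp_spec"] = [asdict(s) for s in self.sim.snp_spec]
        return yaml.safe_dump(d, sort_keys=False)


def default_config(
    n_individuals: int = 50_000,
    n_glu: int = 60,
    n_tg: int = 150,
    seed: int = 0,
    **sim_kwargs,
) -> PipelineConfig:
    """The default study conditions: 60 GLU + 150 TG instruments at n=50,000."""
    spec = make_snp_spec(
        n_glu=n_glu, n_tg=n_tg, n_individuals=n_individuals, seed=seed,
        **{k: sim_kwargs.pop(k) for k in list(sim_kwargs)
           if k in ("n_shared", "n_pleiotropic", "beta_direct", "chi2_per_snp")},
    )
    return PipelineConfig(
        sim=SimConfig(n_individuals=n_individuals, snp_spec=spec, seed=seed, **sim_kwargs)
    )


@dataclass
class PipelineResult:
    """Bundle of every intermediate and final table of one run."""

    config: PipelineConfig
    cohort: Cohort
    qc_table: pd.DataFrame
    scans: dict[str, pd.DataFrame]
    instruments: dict[str, InstrumentSet]
    grs: dict
    grs_r2: dict[str, float]
    independent: pd.DataFrame
    observational: pd.DataFrame | None
    designs: dict[str, dict]
    metareg: object | None
    metareg_tyg: object | None
    continuous: dict[str, object]
    egger: dict[str, object]
    presso: dict[str, dict]
    log: list[dict] = field(default_factory=list)


def _binary_joint_effects(glu_bin, tg_bin, outcome, covars, glu, log_tg,
                          sd_glu, sd_tg) -> pd.DataFrame:
    """Fig.-2-style independent binary-exposure effects, scaled to 1 SD.

    One logistic fit: outcome ~ GLU-high + TG-high + covariates; each
    exposure's log-OR is then rescaled by its crude phenotype difference
    between the high and low halves.
    """
    n = len(outcome)
    x = np.column_stack([np.ones(n), glu_bin, tg_bin, covars])
    res = sm.GLM(np.asarray(outcome, float), x, family=sm.families.Binomial()).fit()
    rows = []
    for i, (name, pheno, target) in enumerate(
        [("glu", glu, sd_glu), ("tg", log_tg, sd_tg)], start=1
    ):
        b, s, p = float(res.params[i]), float(res.bse[i]), float(res.pvalues[i])
        groups = [glu_bin, tg_bin][i - 1]
        delta = float(np.mean(pheno[groups == 1]) - np.mean(pheno[groups == 0]))
        scaled = scale_effect(b, s, delta, target)
        rows.append(
            {
                "exposure": name,
                "log_or": b,
                "se": s,
                "p": p,
                "delta": delta,
                "sd_target": target,
                "scaled_log_or": scaled.log_or,
                "scaled_se": scaled.se,
                "scaled_or": scaled.odds_ratio,
                "scaled_ci_low": scaled.ci_low,
                "scaled_ci_high": scaled.ci_high,
            }
        )
    return pd.DataFrame(rows)


def _cells_with_deltas(effects, assignment_cells, cohort) -> pd.DataFrame:
    tab = effects.table.copy()
    for col, values in (
        ("delta_glu", cohort.glu),
        ("delta_logtg", cohort.log_tg),
        ("delta_tyg", cohort.tyg),
    ):
        deltas = crude_difference(values, assignment_cells, effects.reference)
        tab[col] = tab["cell"].map(deltas)
    return tab


def run_pipeline(config: PipelineConfig, outdir=None, cohort: Cohort | None = None) -> PipelineResult:
    """Execute the full workflow; see module docstring for the stage list."""
    log: list[dict] = []
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.yaml").write_text(config.to_yaml())

    def stage(name):
        t0 = time.perf_counter()

        def done(**counts):
            log.append({"stage": name, "seconds": round(time.perf_counter() - t0, 3), **counts})

        return done

    def run_stage(name, fn):
        try:
            return fn()
        except Exception as e:  # noqa: BLE001 - annotate and re-raise
            _flush_log()
            raise FmrError(f"stage {name!r} failed: {e}") from e

    def _flush_log():
        if outdir is not None:
            lines = ["\t".join(f"{k}={v}" for k, v in rec.items()) for rec in log]
            (outdir / "run.log").write_text("\n".join(lines) + "\n")

    # -- simulate -----------------------------------------------------------
    done = stage("simulate")
    if cohort is None:
        cohort = run_stage("simulate", lambda: simulate_cohort(config.sim))
    done(n=cohort.n, m=len(cohort.snp_ids))

    covars = cohort.covariates[list(config.covariates)].to_numpy()
    scan_covars = cohort.covariates[list(config.scan_covariates)].to_numpy()

    # -- QC -----------------------------------------------------------------
    done = stage("qc")
    qc_report, dos_qc, ids_qc = run_stage(
        "qc",
        lambda: qc_genotypes(
            cohort.dosages, cohort.snp_ids, config.maf_min, config.missing_max,
            config.hwe_alpha,
        ),
    )
    done(snps_in=len(cohort.snp_ids), snps_out=len(ids_qc))
    allele_of = dict(zip(cohort.snp_ids, cohort.effect_alleles))
    other_of = dict(zip(cohort.snp_ids, cohort.other_alleles))
    ea_qc = [allele_of[s] for s in ids_qc]
    oa_qc = [other_of[s] for s in ids_qc]

    # -- association scans --------------------------------------------------
    exposures = {"glu": cohort.glu, "tg": cohort.log_tg}
    if config.include_tyg:
        exposures["tyg"] = cohort.tyg
    scans: dict[str, pd.DataFrame] = {}
    done = stage("scan")
    for name, pheno in exposures.items():
        scans[name] = run_stage(
            f"scan:{name}",
            lambda p=pheno: gwas_scan(dos_qc, p, scan_covars, ids_qc, ea_qc, oa_qc),
        )
    scans["bmi"] = run_stage(
        "scan:bmi",
        lambda: gwas_scan(
            dos_qc, cohort.covariates["bmi"].to_numpy(), scan_covars, ids_qc, ea_qc, oa_qc
        ),
    )
    # linear-model scan of the binary outcome: used only to harmonize
    # exposure instruments against outcome effects for PRESSO/Egger
    scans["outcome"] = run_stage(
        "scan:outcome",
        lambda: gwas_scan(
            dos_qc, cohort.outcome.astype(float), scan_covars, ids_qc, ea_qc, oa_qc
        ),
    )
    done(snps=len(ids_qc), traits=len(scans))

    # -- LD pruning + instrument selection ----------------------------------
    screens_for = {"glu": ["tg", "bmi"], "tg": ["glu", "bmi"], "tyg": ["bmi"]}
    instruments: dict[str, InstrumentSet] = {}
    presso_out: dict[str, dict] = {}
    harmonized: dict[str, HarmonizedData] = {}
    for name in exposures:
        done = stage(f"instruments:{name}")
        pruned_ids = run_stage(
            f"prune:{name}", lambda nm=name: ld_prune(scans[nm], dos_qc, ids_qc, config.r2_max)
        )
        pruned = scans[name].loc[scans[name]["snp"].isin(pruned_ids)].reset_index(drop=True)
        iv = run_stage(
            f"select:{name}",
            lambda tab=pruned, nm=name: select_instruments(
                tab,
                {s: scans[s] for s in screens_for[nm]},
                config.p_gw,
                config.p_pleio,
                exposure=nm,
            ),
        )
        n_selected = len(iv.table)
        harm = HarmonizedData(
            iv.table.merge(
                scans["outcome"][["snp", "beta", "se"]].rename(
                    columns={"beta": "beta_y", "se": "se_y"}
                ),
                on="snp",
            ).rename(columns={"beta": "beta_x", "se": "se_x"})[
                ["snp", "beta_x", "se_x", "beta_y", "se_y"]
            ]
        )
        if config.presso and len(harm) >= 4:
            gp, outliers, _corr = run_stage(
                f"presso:{name}",
                lambda h=harm, nm=name: mr_presso(
                    h, config.presso_nsim, config.presso_alpha,
                    seed=config.sim.seed * 1000 + sum(ord(c) for c in nm),
                ),
            )
            presso_out[name] = {"global_p": gp, "outliers": outliers}
            if outliers:
                iv = iv.drop(outliers, "mr_presso")
                harm = HarmonizedData(
                    harm.table.loc[~harm.table["snp"].isin(outliers)].reset_index(drop=True)
                )
        instruments[name] = iv
        harmonized[name] = harm
        done(candidates=len(scans[name]), pruned=len(pruned), selected=n_selected,
             final=len(iv.table))

    # -- GRS ----------------------------------------------------------------
    done = stage("grs")
    grs_vec = {
        name: run_stage(
            f"grs:{name}",
            lambda nm=name: build_grs(dos_qc, ids_qc, instruments[nm], config.weighted),
        )
        for name in exposures
    }
    grs_r2 = {
        name: variance_explained(grs_vec[name], exposures[name]) for name in exposures
    }
    done(**{f"r2_{k}": round(v, 4) for k, v in grs_r2.items()})

    # -- independent (Fig.-2-style) binary effects --------------------------
    done = stage("independent")
    glu_bin = assign_median_split(grs_vec["glu"].scores)
    tg_bin = assign_median_split(grs_vec["tg"].scores)
    independent = run_stage(
        "independent",
        lambda: _binary_joint_effects(
            glu_bin, tg_bin, cohort.outcome, covars, cohort.glu, cohort.log_tg,
            config.sd_target_glu, config.sd_target_tg,
        ),
    )
    done()

    observational = None
    if config.observational:
        done = stage("observational")
        glu_obs = assign_median_split(cohort.glu)
        tg_obs = assign_median_split(cohort.log_tg)
        observational = run_stage(
            "observational",
            lambda: _binary_joint_effects(
                glu_obs, tg_obs, cohort.outcome, covars, cohort.glu, cohort.log_tg,
                config.sd_target_glu, config.sd_target_tg,
            ),
        )
        done()

    # -- factorial designs --------------------------------------------------
    design_results: dict[str, dict] = {}
    metareg = metareg_tyg = None
    for design in config.designs:
        done = stage(f"design:{design}")
        if design == "tyg_quantiles":
            if not config.include_tyg:
                continue
            groups = assign_quantile_groups(grs_vec["tyg"].scores, config.tyg_k)
            cells = np.array([f"Q{g + 1}" for g in groups])
            eff = run_stage(
                f"design:{design}",
                lambda c=cells: estimate_subgroup_effects(c, cohort.outcome, covars, "Q1"),
            )
            tab = _cells_with_deltas(eff, cells, cohort)
            sub = tab.loc[tab["cell"] != "Q1"]
            metareg_tyg = fit_univariate_metareg(
                sub["delta_tyg"], sub["log_or"], sub["se"]
            )
            design_results[design] = {"effects": eff, "table": tab}
        elif design in ("2x2", "2x4_glu_binary", "2x4_tg_binary", "KxK"):
            assignment = assign_factorial(
                grs_vec["glu"].scores, grs_vec["tg"].scores, design, k=config.kxk
            )
            cells = assignment.cells
            eff = run_stage(
                f"design:{design}",
                lambda c=cells, r=assignment.reference: estimate_subgroup_effects(
                    c, cohort.outcome, covars, r
                ),
            )
            tab = _cells_with_deltas(eff, cells, cohort)
            result = {"effects": eff, "table": tab, "assignment": assignment}
            if design == "2x2":
                gap, gap_se = eff.contrast({"G2_T2": 1.0, "G2_T1": -1.0, "G1_T2": -1.0})
                result["additivity_gap"] = gap
                result["additivity_gap_se"] = gap_se
            if design in ("2x4_glu_binary", "2x4_tg_binary"):
                # binary-exposure effect within each stratum of the other GRS
                bin_grp = assignment.glu_group if design == "2x4_glu_binary" else assignment.tg_group
                strata = assignment.tg_group if design == "2x4_glu_binary" else assignment.glu_group
                strat_effects = []
                for q in sorted(np.unique(strata)):
                    sel = strata == q
                    lab = np.where(bin_grp[sel] == 1, "high", "low")
                    e = estimate_subgroup_effects(
                        lab, cohort.outcome[sel], covars[sel], "low"
                    )
                    b, s = e.effect("high")
                    strat_effects.append({"stratum": f"Q{q + 1}", "log_or": b, "se": s})
                sdf = pd.DataFrame(strat_effects)
                q_stat, dof, q_p = cochran_q(list(zip(sdf["log_or"], sdf["se"])))
                result["strata"] = sdf
                result["heterogeneity"] = {"Q": q_stat, "df": dof, "p": q_p}
            if design == "KxK":
                sub = tab.loc[(tab["cell"] != eff.reference) & tab["estimable"]]
                metareg = fit_bivariate_metareg(
                    sub["delta_glu"], sub["delta_logtg"], sub["log_or"], sub["se"]
                )
                result["joint_1sd"] = predict_joint_effect(
                    metareg, config.sd_target_glu, config.sd_target_tg
                )
            design_results[design] = result
        done()

    # -- continuous two-step MR --------------------------------------------
    continuous: dict[str, object] = {}
    if config.continuous_mr:
        done = stage("continuous_mr")
        for name in exposures:
            continuous[name] = run_stage(
                f"continuous:{name}",
                lambda nm=name: continuous_grs_mr(
                    grs_vec[nm], exposures[nm], cohort.outcome, covars
                ),
            )
        done()

    # -- Egger diagnostics --------------------------------------------------
    egger: dict[str, object] = {}
    if config.egger:
        done = stage("egger")
        for name in exposures:
            if len(harmonized[name]) >= 3:
                egger[name] = run_stage(
                    f"egger:{name}", lambda nm=name: mr_egger(harmonized[nm])
                )
        done()

    result = PipelineResult(
        config=config,
        cohort=cohort,
        qc_table=qc_report.table,
        scans=scans,
        instruments=instruments,
        grs=grs_vec,
        grs_r2=grs_r2,
        independent=independent,
        observational=observational,
        designs=design_results,
        metareg=metareg,
        metareg_tyg=metareg_tyg,
        continuous=continuous,
        egger=egger,
        presso=presso_out,
        log=log,
    )
    if outdir is not None:
        _write_outputs(result, outdir)
        _flush_log()
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    result.qc_table.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    for name, scan in result.scans.items():
        fio.write_summary_stats(outdir / f"scan_{name}.tsv", scan)
    for name, iv in result.instruments.items():
        fio.write_summary_stats(outdir / f"instruments_{name}.tsv", iv.table)
        iv.exclusions.to_csv(outdir / f"exclusions_{name}.tsv", sep="\t", index=False)
    for name, g in result.grs.items():
        pd.DataFrame(
            {
                "iid": [f"id{i:07d}" for i in range(len(g.scores))],
                "score": g.scores,
                "exposure": g.exposure,
                "weighted": g.weighted,
                "n_snps": g.n_snps,
            }
        ).to_csv(outdir / f"grs_{name}.tsv", sep="\t", index=False)
    result.independent.to_csv(outdir / "independent_effects.tsv", sep="\t", index=False)
    if result.observational is not None:
        result.observational.to_csv(
            outdir / "observational_effects.tsv", sep="\t", index=False
        )
    for design, res in result.designs.items():
        res["table"].to_csv(outdir / f"subgroups_{design}.tsv", sep="\t", index=False)
    for label, mr in (("metareg_glu_tg", result.metareg), ("metareg_tyg", result.metareg_tyg)):
        if mr is not None:
            rows = [
                {"term": t, "estimate": float(mr.coef[i]), "se": float(mr.se[i]),
                 "p": float(mr.pvalues[i])}
                for i, t in enumerate(mr.terms)
            ]
            pd.DataFrame(rows).to_csv(outdir / f"{label}.tsv", sep="\t", index=False)
    if result.continuous:
        pd.DataFrame(
            [
                {"exposure": k, "log_or_per_sd": v.estimate, "se": v.se, "p": v.p,
                 "stage1_f": v.diagnostics.get("stage1_f"),
                 "warnings": ";".join(v.warnings)}
                for k, v in result.continuous.items()
            ]
        ).to_csv(outdir / "continuous_mr.tsv", sep="\t", index=False)
    if result.egger:
        pd.DataFrame(
            [
                {"exposure": k, "slope": v.estimate, "slope_se": v.se,
                 "intercept": v.intercept, "intercept_se": v.intercept_se,
                 "intercept_p": v.intercept_p}
                for k, v in result.egger.items()
            ]
        ).to_csv(outdir / "egger.tsv", sep="\t", index=False)
    fio.write_truth(outdir / "truth.txt", result.cohort.truth)
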