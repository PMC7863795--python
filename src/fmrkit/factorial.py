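"""Factorial "genetic randomization": subgroup assignment, adjusted subgroup
effects, crude phenotype differences, heterogeneity/interaction tests, and
1-SD scaling of subgroup odds ratios.

The cohort is partitioned by the median or quantiles of one or two genetic
risk scores, emulating a factorial randomized trial; per-cell effects come
from one multivariable logistic fit with indicator variables against the
reference cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ConfigError, DomainError, EstimationError

__all__ = [
    "FactorialAssignment",
    "SubgroupEffects",
    "ScaledEffect",
    "assign_median_split",
    "assign_quantile_groups",
    "assign_factorial",
    "estimate_subgroup_effects",
    "crude_difference",
    "scale_effect",
    "cochran_q",
    "interaction_z",
]

Z95 = stats.norm.ppf(0.975)


def assign_median_split(scores) -> np.ndarray:
    """0/1 groups: 0 iff score <= sample median (ties go low), else 1."""
    s = np.asarray(scores, dtype=float)
    if len(s) < 2:
        raise ConfigError("need at least 2 individuals to split")
    if np.all(s == s[0]):
        raise EstimationError("all scores equal; median split degenerate")
    return (s > np.median(s)).astype(int)


def assign_quantile_groups(scores, k: int) -> np.ndarray:
    """Ordinal groups 0..k-1 cut at sample quantiles i/k; ties go low.

    k=2 reproduces `assign_median_split` exactly.
    """
    s = np.asarray(scores, dtype=float)
    if k < 2:
        raise ConfigError("k must be >= 2")
    if len(s) < k:
        raise ConfigError("need n >= k individuals")
    if np.all(s == s[0]):
        raise EstimationError("all scores equal; quantile grouping degenerate")
    cuts = np.quantile(s, np.arange(1, k) / k)
    return np.searchsorted(cuts, s, side="left").astype(int)


@dataclass
class FactorialAssignment:
    """Per-individual cross-classified groups for a factorial design."""

    glu_group: np.ndarray
    tg_group: np.ndarray
    design: str  # 2x2 | 2x4_glu_binary | 2x4_tg_binary | KxK

    @property
    def cells(self) -> np.ndarray:
        """String cell labels 'G{i}_T{j}' with 1-based ordinal indices."""
        return np.array(
            [f"G{g + 1}_T{t + 1}" for g, t in zip(self.glu_group, self.tg_group)]
        )

    @property
    def reference(self) -> str:
        return "G1_T1"


def assign_factorial(
    grs_glu,
    grs_tg,
    design: str = "2x2",
    k: int = 3,
    nested: bool = False,
) -> FactorialAssignment:
    """Cross-classify individuals by two GRS vectors.

    Designs: ``2x2`` (median x median), ``2x4_glu_binary`` (GLU median, TG
    quartiles), ``2x4_tg_binary`` (TG median, GLU quartiles), ``KxK``
    (quantiles of both, `k` in {3, 4, ...}). With `nested=True` the 2x2
    second split uses the median within each first-split half (the
    sequential description of the design); the default is independent
    marginal splits, identical up to ties.
    """
    g = np.asarray(getattr(grs_glu, "scores", grs_glu), dtype=float)
    t = np.asarray(getattr(grs_tg, "scores", grs_tg), dtype=float)
    if len(g) != len(t):
        raise ConfigError("the two GRS vectors must cover the same individuals")
    if design == "2x2":
        gg = assign_median_split(g)
        if nested:
            tt = np.empty(len(t), dtype=int)
            for half in (0, 1):
                idx = gg == half
                tt[idx] = assign_median_split(t[idx])
        else:
            tt = assign_median_split(t)
    elif design == "2x4_glu_binary":
        gg, tt = assign_median_split(g), assign_quantile_groups(t, 4)
    elif design == "2x4_tg_binary":
        gg, tt = assign_quantile_groups(g, 4), assign_median_split(t)
    elif design == "KxK":
        gg, tt = assign_quantile_groups(g, k), assign_quantile_groups(t, k)
    else:
        raise ConfigError(f"unknown design {design!r}")
    return FactorialAssignment(gg, tt, design)


@dataclass
class SubgroupEffects:
    """Adjusted per-cell effects from one logistic fit.

    `table` columns: cell, n, n_cases, log_or, se, or, ci_low, ci_high, p,
    estimable. The reference row has log_or 0 and NaN inference fields.
    `cov` is the covariance of the non-reference cell coefficients, used for
    contrasts such as the log-additivity gap.
    """

    table: pd.DataFrame
    cov: pd.DataFrame
    reference: str

    def effect(self, cell: str) -> tuple[float, float]:
        row = self.table.set_index("cell").loc[cell]
        return float(row["log_or"]), float(row["se"])

    def contrast(self, coeffs: dict[str, float]) -> tuple[float, float]:
        """Estimate and SE of a linear combination of cell log-ORs."""
        cells = [c for c in coeffs if c != self.reference]
        c = np.array([coeffs[c] for c in cells])
        est = float(
            sum(coeffs[cell] * self.effect(cell)[0] for cell in coeffs)
        )
        v = self.cov.loc[cells, cells].to_numpy()
        return est, float(math.sqrt(c @ v @ c))


def estimate_subgroup_effects(
    cells: Sequence[str] | np.ndarray,
    outcome,
    covariates: pd.DataFrame | np.ndarray | None = None,
    reference: str | None = None,
) -> SubgroupEffects:
    """One ML logistic fit with an indicator per non-reference cell.

    Cells that are empty or contain a single outcome class are flagged
    non-estimable and their individuals are dropped from the fit; the fit
    proceeds for the remaining cells. Wald 95% CIs on the OR scale.
    """
    cells = np.asarray(cells)
    y = np.asarray(outcome, dtype=float)
    labels = sorted(pd.unique(cells))
    if reference is None:
        reference = labels[0]
    if reference not in labels:
        raise ConfigError(f"reference cell {reference!r} not present")

    counts = {
        lab: (int((cells == lab).sum()), int(y[cells == lab].sum())) for lab in labels
    }
    n_ref, cases_ref = counts[reference]
    if n_ref == 0 or cases_ref in (0, n_ref):
        raise EstimationError("reference cell empty or single-class")
    estimable = {
        lab: (counts[lab][0] > 0 and 0 < counts[lab][1] < counts[lab][0])
        for lab in labels
    }
    estimable[reference] = True

    keep = np.array([estimable[lab] for lab in cells])
    fit_cells, fit_y = cells[keep], y[keep]
    model_labels = [lab for lab in labels if estimable[lab] and lab != reference]
    x_parts = [np.ones(len(fit_y))]
    names = ["const"]
    for lab in model_labels:
        x_parts.append((fit_cells == lab).astype(float))
        names.append(lab)
    if covariates is not None:
        cmat = np.asarray(covariates, dtype=float)
        cnames = (
            list(covariates.columns)
            if isinstance(covariates, pd.DataFrame)
            else [f"x{i}" for i in range(cmat.shape[1])]
        )
        x_parts.append(cmat[keep])
        names.extend(cnames)
    x = np.column_stack(x_parts)
    res = sm.GLM(fit_y, x, family=sm.families.Binomial()).fit()
    params = dict(zip(names, res.params))
    bse = dict(zip(names, res.bse))
    pvals = dict(zip(names, res.pvalues))

    rows = []
    for lab in labels:
        n_lab, cases_lab = counts[lab]
        if lab == reference:
            rows.append(
                dict(cell=lab, n=n_lab, n_cases=cases_lab, log_or=0.0, se=np.nan,
                     odds_ratio=1.0, ci_low=np.nan, ci_high=np.nan, p=np.nan,
                     estimable=True)
            )
        elif not estimable[lab]:
            rows.append(
                dict(cell=lab, n=n_lab, n_cases=cases_lab, log_or=np.nan, se=np.nan,
                     odds_ratio=np.nan, ci_low=np.nan, ci_high=np.nan, p=np.nan,
                     estimable=False)
            )
        else:
            b, s = params[lab], bse[lab]
            rows.append(
                dict(cell=lab, n=n_lab, n_cases=cases_lab, log_or=b, se=s,
                     odds_ratio=math.exp(b), ci_low=math.exp(b - Z95 * s),
                     ci_high=math.exp(b + Z95 * s), p=pvals[lab], estimable=True)
            )
    cov_full = pd.DataFrame(res.cov_params(), index=names, columns=names)
    cov = cov_full.loc[model_labels, model_labels]
    return SubgroupEffects(pd.DataFrame(rows), cov, reference)


def crude_difference(phenotype, cells, reference: str | None = None) -> pd.Series:
    """Crude mean difference of a phenotype per cell vs the reference cell.

    Empty groups get NaN.
    """
    v = np.asarray(phenotype, dtype=float)
    cells = np.asarray(cells)
    labels = sorted(pd.unique(cells))
    if reference is None:
        reference = labels[0]
    ref_mean = float(v[cells == reference].mean())
    out = {}
    for lab in labels:
        sel = cells == lab
        out[lab] = float(v[sel].mean() - ref_mean) if sel.any() else np.nan
    return pd.Series(out, name="delta")


@dataclass
class ScaledEffect:
    """A subgroup log-OR rescaled to a target exposure difference (e.g. 1 SD)."""

    log_or: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    factor: float


def scale_effect(log_or: float, se: float, delta_obs: float, sd_target: float) -> ScaledEffect:
    """Rescale (log_or, se) from the observed crude difference to `sd_target`.

    factor = sd_target / delta_obs multiplies both the log-OR and its SE;
    OR and 95% CI by exponentiation.
    """
    if delta_obs == 0:
        raise DomainError("delta_obs is zero: effect cannot be rescaled")
    f = sd_target / delta_obs
    b, s = f * log_or, abs(f) * se
    return ScaledEffect(b, s, math.exp(b), math.exp(b - Z95 * s), math.exp(b + Z95 * s), f)


def cochran_q(effects: Sequence[tuple[float, float]]) -> tuple[float, int, float]:
    """Cochran heterogeneity Q over (log_or, se) pairs; p from chi2(G-1)."""
    effects = list(effects)
    if len(effects) < 2:
        raise ConfigError("need at least 2 effects for the Q test")
    est = np.array([e[0] for e in effects], dtype=float)
    se = np.array([e[1] for e in effects], dtype=float)
    if (se <= 0).any():
        raise ConfigError("all SEs must be > 0")
    w = 1.0 / se**2
    mean_w = float((w * est).sum() / w.sum())
    q = float((w * (est - mean_w) ** 2).sum())
    dof = len(effects) - 1
    return q, dof, float(stats.chi2.sf(q, dof))


def interaction_z(
    effect_a: tuple[float, float], effect_b: tuple[float, float]
) -> tuple[float, float]:
    """z-test for the difference between two independent log-ORs."""
    (ta, sa), (tb, sb) = effect_a, effect_b
    if sa <= 0 or sb <= 0:
        raise ConfigError("SEs must be > 0")
    z = (ta - tb) / math.sqrt(sa**2 + sb**2)
    return z, float(2 * stats.norm.sf(abs(z)))
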