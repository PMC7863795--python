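"""Dose-response meta-regression across the factorial grid.

Regresses per-cell log odds ratios on the crude phenotype differences
(ΔGLU, Δlog TG) — or ΔTyG in the univariate variant — by fixed-effect
weighted least squares through the origin (the reference cell sits at
Δ = 0, log-OR = 0 by construction). The fitted plane predicts the causal
effect of any (ΔGLU, Δlog TG) combination, e.g. the joint 1-SD pair
(0.62 mmol/L, 0.50 log mmol/L).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigError, EstimationError

__all__ = [
    "MetaRegResult",
    "PredictedEffect",
    "fit_bivariate_metareg",
    "fit_univariate_metareg",
    "predict_joint_effect",
]

Z95 = stats.norm.ppf(0.975)


@dataclass
class MetaRegResult:
    """Fixed-effect meta-regression fit: coefficients, covariance, Wald tests."""

    terms: tuple[str, ...]
    coef: np.ndarray
    cov: np.ndarray  # symmetric PSD coefficient covariance
    se: np.ndarray
    pvalues: np.ndarray
    model_p: float  # joint Wald test that all coefficients are zero
    tau2: float = 0.0

    def coefficient(self, term: str) -> tuple[float, float, float]:
        i = self.terms.index(term)
        return float(self.coef[i]), float(self.se[i]), float(self.pvalues[i])


def _fit_metareg(x: np.ndarray, y: np.ndarray, se: np.ndarray, terms, method: str):
    if x.ndim == 1:
        x = x[:, None]
    ok = np.isfinite(y) & np.isfinite(se) & np.all(np.isfinite(x), axis=1) & (se > 0)
    x, y, se = x[ok], y[ok], se[ok]
    p = x.shape[1]
    if len(y) < p + 1:
        raise ConfigError(f"need at least {p + 1} informative cells, got {len(y)}")
    if np.linalg.matrix_rank(x) < p:
        raise EstimationError(
            "design deficient: the cell deltas are collinear, coefficients not identifiable"
        )
    tau2 = 0.0
    if method == "dl":
        # DerSimonian-Laird moment estimator from the fixed-effect residual Q
        coef_fe, _ = _wls(x, y, 1.0 / se**2)
        w = 1.0 / se**2
        q = float((w * (y - x @ coef_fe) ** 2).sum())
        c = float(w.sum() - (w**2).sum() / w.sum())
        tau2 = max(0.0, (q - (len(y) - p)) / c) if c > 0 else 0.0
    elif method != "fixed":
        raise ConfigError(f"unknown method {method!r}")
    w = 1.0 / (se**2 + tau2)
    coef, cov = _wls(x, y, w)
    se_c = np.sqrt(np.diag(cov))
    pv = 2 * stats.norm.sf(np.abs(coef) / se_c)
    wald = float(coef @ np.linalg.solve(cov, coef))
    model_p = float(stats.chi2.sf(wald, p))
    return MetaRegResult(tuple(terms), coef, cov, se_c, pv, model_p, tau2)


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(x * sw[:, None], y * sw, rcond=None)
    cov = np.linalg.pinv(x.T @ (x * w[:, None]))
    return coef, cov


def fit_bivariate_metareg(
    delta_glu,
    delta_logtg,
    log_or,
    se,
    method: str = "fixed",
) -> MetaRegResult:
    """WLS of cell log-ORs on (ΔGLU, Δlog TG) with weights 1/se², no intercept.

    The reference cell (0, 0, 0) is consistent with the origin constraint and
    carries no information, so rows with NaN SE (the reference) are dropped.
    `method="dl"` adds a DerSimonian-Laird between-cell variance tau².
    """
    x = np.column_stack(
        [np.asarray(delta_glu, float), np.asarray(delta_logtg, float)]
    )
    return _fit_metareg(
        x, np.asarray(log_or, float), np.asarray(se, float), ("glu", "tg"), method
    )


def fit_univariate_metareg(delta, log_or, se, term: str = "tyg", method: str = "fixed") -> MetaRegResult:
    """Univariate analogue (e.g. log-OR on ΔTyG)."""
    return _fit_metareg(
        np.asarray(delta, float), np.asarray(log_or, float), np.asarray(se, float),
        (term,), method,
    )


@dataclass
class PredictedEffect:
    log_or: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float


def predict_joint_effect(result: MetaRegResult, *deltas: float) -> PredictedEffect:
    """Predicted OR (95% CI) at a delta combination, e.g. (0.62, 0.50).

    log-OR = x'b; variance by the quadratic form with the coefficient
    covariance; linear in the deltas on the log-OR scale.
    """
    x = np.asarray(deltas, dtype=float)
    if len(x) != len(result.terms):
        raise ConfigError(f"expected {len(result.terms)} deltas, got {len(x)}")
    b = float(x @ result.coef)
    var = float(x @ result.cov @ x)
    s = math.sqrt(max(var, 0.0))
    return PredictedEffect(
        b, s, math.exp(b), math.exp(b - Z95 * s), math.exp(b + Z95 * s)
    )
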