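"""Genetic risk score construction and instrument-strength diagnostics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .assoc import InstrumentSet
from .errors import ConfigError, EstimationError

__all__ = ["GRSVector", "build_grs", "variance_explained", "cv_auc"]


@dataclass
class GRSVector:
    """Per-individual genetic risk score with provenance metadata."""

    scores: np.ndarray
    exposure: str
    weighted: bool
    n_snps: int

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.isfinite(self.scores).all():
            raise ConfigError("GRS contains non-finite values")

    def __len__(self) -> int:
        return len(self.scores)


def build_grs(
    dosages: np.ndarray,
    snp_ids,
    instruments: InstrumentSet,
    weighted: bool = True,
) -> GRSVector:
    """Sum of exposure-increasing allele dosages, beta-weighted or unit-weighted.

    Each SNP's counted allele is oriented to the exposure-increasing allele:
    a SNP with beta < 0 has its dosage flipped d -> 2-d and contributes with
    weight |beta| (or 1 when unweighted). Missing dosages — including
    instrument SNPs absent from the matrix entirely — contribute zero.
    """
    if instruments.table.empty:
        raise EstimationError("empty instrument set")
    dosages = np.asarray(dosages, dtype=float)
    n = dosages.shape[0]
    col = {s: j for j, s in enumerate(snp_ids)}
    score = np.zeros(n)
    used = 0
    for _, row in instruments.table.iterrows():
        j = col.get(row["snp"])
        if j is None:
            continue  # absent SNP == all-missing == contributes zero
        d = dosages[:, j]
        if row["beta"] < 0:
            d = 2.0 - d
        w = abs(row["beta"]) if weighted else 1.0
        score += w * np.nan_to_num(d, nan=0.0)
        used += 1
    return GRSVector(score, instruments.exposure, weighted, used)


def variance_explained(score: GRSVector | np.ndarray, phenotype) -> float:
    """R-squared of the OLS regression phenotype ~ score."""
    s = score.scores if isinstance(score, GRSVector) else np.asarray(score, float)
    y = np.asarray(phenotype, dtype=float)
    if len(s) != len(y) or len(s) < 3:
        raise ConfigError("score and phenotype must have equal length >= 3")
    if np.var(s) == 0:
        raise EstimationError("zero-variance score: R^2 undefined")
    r = np.corrcoef(s, y)[0, 1]
    return float(r * r)


def cv_auc(
    score: GRSVector | np.ndarray,
    binary_phenotype,
    k: int = 10,
    seed: int = 0,
) -> float:
    """Mean held-out AUC of the raw score over stratified k-fold CV.

    The score itself is the classifier (no model is fitted), so the folds
    only determine which individuals each AUC is evaluated on.
    """
    s = score.scores if isinstance(score, GRSVector) else np.asarray(score, float)
    y = np.asarray(binary_phenotype, dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise EstimationError("binary phenotype has a single class; AUC undefined")
    if np.all(s == s[0]):
        return 0.5  # constant score carries no ranking information
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    aucs = [
        roc_auc_score(y[test_idx], s[test_idx])
        for _, test_idx in skf.split(s.reshape(-1, 1), y)
    ]
    return float(np.mean(aucs))
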