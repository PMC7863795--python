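import numpy as np
import pandas as pd
import pytest

import fmrkit as fk


@pytest.fixture(scope="session")
def small_cohort() -> fk.Cohort:
    """A modest cohort reused across read-only tests (n=6000, 12+18 SNPs)."""
    spec = fk.make_snp_spec(
        n_glu=12, n_tg=18, n_individuals=6000, chi2_per_snp=80, seed=11
    )
    cfg = fk.SimConfig(n_individuals=6000, snp_spec=spec, seed=42)
    return fk.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def big_cohort() -> fk.Cohort:
    """A full-scale cohort for variance-decomposition and recovery checks."""
    cfg = fk.default_config(n_individuals=50_000, seed=5).sim
    return fk.simulate_cohort(cfg)


def make_summary(snps, pvals, betas=None, ses=None, eaf=0.3, n=10_000,
                 effect="A", other="G") -> pd.DataFrame:
    """Hand-built SummaryStats frame with self-consistent beta/se/p."""
    from scipy import stats

    pvals = np.asarray(pvals, dtype=float)
    if ses is None:
        ses = np.full(len(snps), 0.01)
    ses = np.asarray(ses, dtype=float)
    if betas is None:
        betas = stats.norm.isf(pvals / 2.0) * ses  # exactly consistent
    return pd.DataFrame(
        {
            "snp": list(snps),
            "effect_allele": [effect] * len(snps),
            "other_allele": [other] * len(snps),
            "eaf": eaf,
            "beta": np.asarray(betas, dtype=float),
            "se": ses,
            "pval": pvals,
            "n": n,
        }
    )
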