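# fmrkit — factorial Mendelian randomization toolkit

`fmrkit` is a Python library for **factorial Mendelian randomization (MR)**:
using genetic risk scores (GRS) as instruments of randomization to estimate
the independent and joint causal effects of two correlated exposures —
circulating glucose (GLU, mmol/L) and log triglyceride (log TG) — on binary
cardiometabolic outcomes, together with the TyG insulin-resistance index
`TyG = ln(TG[mg/dl] × GLU[mg/dl] / 2)`. It is aimed at biostatisticians and
genetic epidemiologists who want a tested, reproducible implementation of the
whole workflow on individual-level data, plus the summary-level MR estimators
used to clean and verify the instruments.

## What it implements

- **Synthetic cohort generator** (`fmrkit.simulate`): independent biallelic
  SNPs with trait-specific, shared and directly pleiotropic effects;
  phenotypes with covariate, hidden-confounder and residual components
  calibrated so SD(GLU) = 0.62 mmol/L and SD(log TG) = 0.50; a logistic
  outcome model with configurable 1-SD causal odds ratios; and a lossless
  ground-truth ledger for parameter-recovery testing.
- **Instrument workflow** (`fmrkit.assoc`, `fmrkit.grs`): per-SNP QC
  (MAF > 0.01, missingness < 0.05, Hardy–Weinberg p ≥ 1e−5), a
  covariate-adjusted association scan, greedy LD pruning at r² < 0.01,
  selection at p < 5×10⁻⁸ with cross-trait/confounder screens at p < 10⁻⁷,
  and weighted/unweighted GRS with variance-explained and 10-fold-CV AUC
  diagnostics.
- **Factorial MR** (`fmrkit.factorial`): median/quantile GRS splits (2×2,
  2×4, K×K, TyG quartiles), per-cell adjusted log-ORs from one logistic fit,
  crude phenotype differences, Cochran Q and interaction z-tests, and 1-SD
  rescaling `log OR × (SD_target / Δ_observed)`.
- **Dose–response meta-regression** (`fmrkit.doseresponse`): fixed-effect WLS
  of cell log-ORs on (ΔGLU, Δlog TG) through the origin, with prediction of
  the effect of any exposure combination and a univariate TyG analogue.
- **Summary-level MR** (`fmrkit.summarymr`): allele harmonization, Wald
  ratios, fixed-effect IVW
  `θ̂ = Σ wⱼ (β_Yⱼ/β_Xⱼ) / Σ wⱼ`, `wⱼ = β_Xⱼ²/σ_Yⱼ²`,
  MR-Egger with its directional-pleiotropy intercept test, the MR-PRESSO
  simulation-based outlier search, multivariable MR, and a continuous-GRS
  two-step MR for individual-level data.
- **Pipeline** (`fmrkit.pipeline`, `fmrkit.io`): one call from simulation to
  every result table, with TSV/VCF I/O, filter-provenance logging and
  byte-reproducible runs given a seed.

## Worked example

```python
import fmrkit as fk

config = fk.default_config(n_individuals=30_000, seed=11)
res = fk.run_pipeline(config)
print(res.independent[["exposure", "delta", "scaled_or",
                       "scaled_ci_low", "scaled_ci_high"]])
```

prints (see `examples/factorial_analysis.py` for the full script):

```
exposure  delta  scaled_or  scaled_ci_low  scaled_ci_high
     glu  0.384      1.096          0.999           1.203
      tg  0.505      1.290          1.218           1.366
generative truth: GLU 1.20, TG 1.32
```

`delta` is the crude phenotype difference between the high- and low-GRS
halves; the odds ratio of the marginal logistic comparison is rescaled by
`0.62/delta` (GLU) or `0.50/delta` (TG) to a per-1-SD effect, which should —
and does — bracket the generative truth. The same run reports the 2×2 cell
ORs (joint high/high cell 1.37, consistent with log-additivity: gap −0.006,
SE 0.059), the 2×4 heterogeneity Q-test (p = 0.99, no effect modification
across strata), and the observational analogue (phenotype-median splits),
whose scaled ORs (1.38 / 1.49) absorb the planted confounder and overshoot
the truth — the contrast factorial MR exists to avoid.

Each `examples/*.py` script is a short narrative for one capability:
cohort simulation, instrument selection, factorial analysis, dose–response
meta-regression, summary-level MR, and the full pipeline.

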