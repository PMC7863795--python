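# Methods

## The estimand and the design

Factorial MR treats two genetic risk scores as instruments of randomization:
splitting a cohort at the medians (or quantiles) of the GLU-GRS and TG-GRS
emulates a 2×2 (or K×K) factorial trial of lifelong exposure to higher
glucose and higher triglyceride. Within each cell, a single multivariable
logistic regression with indicator variables against the reference cell
(low/low) and covariates (age, sex, BMI, smoking status, fasting time, LDL)
yields adjusted log odds ratios with Wald standard errors. Because a GRS
difference moves the phenotype by only a fraction of its SD, each subgroup
log-OR is rescaled by the observed crude phenotype difference Δ between the
compared groups: `scaled log-OR = log-OR × SD_target/Δ`, with SD targets
0.62 mmol/L (GLU) and 0.50 (log TG) — the phenotype SDs the generator is
calibrated to. Both the estimate and its SE scale by the same factor;
uncertainty in Δ itself is ignored (at n = 50,000 its relative SE is ~1–2%,
negligible against the log-OR's).

## The generative model

Genotypes are independent `Binomial(2, MAF)` dosages (an optional
Gaussian-copula block mode induces within-block LD solely to exercise
pruning). Phenotypes are linear:

```
GLU_i = μ_G + Σ_j β_Gj d_ij + Σ_c γ_Gc (x_ic − x̄_c) + δ_G U_i + ε_Gi
```

and analogously for log TG; `U ~ N(0,1)` is a hidden confounder retained
only in the truth ledger, and residual SDs are solved by variance
decomposition so the total SDs hit 0.62 / 0.50. TyG is deterministic:
`ln(TG·88.57 × GLU·18.0182 / 2)` (standard mmol/L→mg/dl conversions). The
outcome is Bernoulli with logit linear in GLU, log TG, covariates, U, and
any per-SNP direct effects (horizontal pleiotropy); the intercept is solved
by root-finding so the expected prevalence equals a target (default 0.20, a
plausible broad-CVD prevalence in a middle-aged cohort). Causal effects are
parameterized as 1-SD ORs: `θ_GLU = ln(1.20)/0.62`, `θ_TG = ln(1.32)/0.50`
by default.

Covariate marginals: age ~ U(40,69) years, sex ~ Bern(0.5),
BMI ~ N(27,4) kg/m², smoking ~ Bern(0.1), fasting time ~ U(0,24) h,
LDL ~ N(3.5,0.8) mmol/L; their effects on the phenotypes and outcome are
small, configurable, and applied to mean-centred values.

### Instrument-strength calibration

Per-SNP effect sizes from `make_snp_spec` are sized so each SNP's expected
association χ² at the simulated sample size is 80 (z ≈ 8.9). This is a
deliberate scaled-down-study choice: the workflow's own selection step
requires instruments to clear p < 5×10⁻⁸ at the simulated n, exactly as a
biobank-scale study's instruments clear it at biobank n. Holding instead the
biobank-scale *variance explained* fixed (a few percent spread over dozens
of SNPs) would leave every per-SNP test at χ² ≈ 20 and the selection stage
empty at n = 50,000 — the design would not run at all. The consequence is a
GRS explaining ~10% (GLU, 60 SNPs) and ~24% (TG, 150 SNPs) of phenotype
variance at the default panel sizes, larger than real glycemic/lipid scores;
what is preserved is the *structure* of the analysis (selection, winner's
curse essentially absent in both regimes, scaling by observed Δ), not the
absolute instrument strength.

### Confounding defaults

`U` shifts GLU by 0.25 mmol/L (~0.4 SD) and log TG by 0.25 (~0.5 SD) per
unit and adds 0.3 to the outcome log-odds — a strong but realistic
unmeasured lifestyle/adiposity-style confounder. It biases the
phenotype-split ("observational") analysis upward by ~0.1–0.25 on the scaled
log-OR scale while leaving the GRS-split analysis unbiased, which is the
contrast the test suite quantifies.

## Estimators

- **IVW** is fixed-effect with first-order weights `β_X²/σ_Y²`; with one SNP
  it reduces exactly to the Wald ratio.
- **MR-Egger** first orients all SNPs to non-negative exposure betas (needed
  for identifiability of the intercept), then fits WLS with weights `1/σ_Y²`
  and multiplicative overdispersion (t-based inference). Under no pleiotropy
  with correct σ_Y the intercept test holds its 5% level exactly.
- **MR-PRESSO** computes leave-one-out IVW residual contributions
  `w_j (β_Yj − θ̂_(−j) β_Xj)²`, simulates the null by parametric draws of
  (β_X*, β_Y*) with each simulated dataset contributing its own
  leave-one-out RSS, and flags SNPs whose empirical contribution p-value,
  Bonferroni-multiplied by m, falls below α (defaults n_sim = 1000,
  α = 0.05). The empirical p can be exactly zero when the observed
  contribution exceeds every simulated one. The distortion test is out of
  scope; PRESSO is used only to remove outliers before GRS construction.
- **MVMR** regresses outcome betas on both exposures' betas through the
  origin with weights `1/σ_Y²`; an identically-zero second exposure reduces
  to univariate IVW.
- **Continuous two-step MR** fits OLS phenotype ~ GRS + covariates, then
  logistic outcome ~ fitted exposure + covariates, reporting the effect per
  phenotype SD. The SE is the stage-2 Wald SE (first-order two-stage
  approximation; with stage-1 F in the hundreds the neglected stage-1 term
  is immaterial). F < 10 raises a weak-instrument warning.
- **Meta-regression** is fixed-effect WLS without intercept: the reference
  cell sits at (Δ = 0, log-OR = 0) by construction, so the plane is forced
  through the origin (configurable). Regression is on the log-OR scale. A
  DerSimonian–Laird additive τ² option exists but is off by default — no
  between-cell heterogeneity model is assumed.

## Numerical and convention choices

- Median/quantile splits send boundary ties to the lower group; greedy LD
  pruning visits SNPs by ascending p then lexicographic id, making results
  order-independent.
- The 2×2 split uses independent marginal medians (the sequential
  split-within-half variant is available via `nested=True`); the two agree
  up to ties and the marginal version is reproducible irrespective of
  processing order.
- GWAS scanning uses closed-form Frisch–Waugh residualization when no
  dosages are missing (identical to per-SNP full OLS, t-based p-values) and
  per-SNP complete-case OLS otherwise. Constant-dosage and perfect-fit
  columns are flagged, not fatal.
- Inside the pipeline the *outcome-side* per-SNP scan (needed only to
  harmonize instruments against outcome effects for PRESSO/Egger) is linear
  regression of the 0/1 outcome; linear-probability betas are locally
  proportional to log-odds betas and adequate for outlier/pleiotropy
  screening.
- Missing dosages contribute zero to a GRS (and an instrument SNP absent
  from the genotype matrix contributes zero for everyone); in scans they
  drop the individual for that SNP only.
- Logistic cells that are empty or single-class are flagged non-estimable
  and excluded from the fit; the reference cell must be estimable.
- All stochastic procedures take explicit seeds; a pipeline run writes
  byte-identical outputs given the same config and seed.

## What the tests show — and what they do not

The acceptance-style suite runs 20 seeded replicates of the full pipeline at
n = 50,000 with 60 + 150 instruments and verifies: 95% CI coverage of the
true 1-SD ORs in ≥ 18/20 runs with the replicate-mean within 10% of truth on
the log-OR scale; ≥ 3× larger bias in the observational analogue; and a mean
2×2 log-additivity gap within 2 Monte-Carlo SEs of zero. Meta-regression is
checked for exact recovery on noiseless grids and 93–97% prediction coverage
over 300 noisy grids; Egger calibration over 500 summary-level replicates;
PRESSO power (10×-inflated SNP flagged in ≥ 95/100 replicates) and null
behaviour; filter thresholds at exact boundaries; and KS-uniformity of
Cochran-Q and scan null p-values over 1000 replicates. Problem sizes were
chosen as the smallest at which these are sharp statistical statements.

The generator emulates the *statistical* structure of a biobank factorial MR
— not real LD, population structure, relatedness, phenotype measurement
error, ICD-based outcome definitions, or selection ("healthy volunteer")
effects. A small (~3%) attenuation of marginal logistic estimates relative
to the conditional generative parameter is inherent to odds-ratio
non-collapsibility and affects the real analysis equally; it is visible in
the recovery tests as a slight downward shift well inside the tolerance.
Passing tests therefore demonstrate correctness and calibration of the
estimators under the stated model, not robustness to the un-modelled
features of real cohort data.

## Known limitations

- No BGEN/imputation-INFO handling; genotypes are abstract dosages.
- No weighted-median/mode or radial MR estimators; no MR-PRESSO distortion
  test; no survival outcomes (logistic ORs only, matching the design).
- The AUC diagnostic dichotomizes continuous phenotypes at the median
  (configurable); other clinically motivated cutpoints would change its
  absolute value but not the GRS comparison.
- The phenotypic GLU–TG correlation is a free parameter (via shared SNPs,
  shared covariates and the confounder), not fixed to a reference value.
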