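"""Factorial MR: 2x2 genetic randomization, scaling to 1-SD odds ratios.

Median splits of the two genetic risk scores emulate a 2x2 factorial trial
of lifelong glucose and triglyceride exposure. Cell effects come from one
logistic fit adjusted for age, sex, BMI, smoking, fasting time and LDL;
each marginal effect is rescaled by the crude phenotype difference between
the score halves to a 1-SD (0.62 mmol/L GLU / 0.50 log TG) odds ratio.
"""

import numpy as np

import fmrkit as fk

config = fk.default_config(n_individuals=30_000, seed=11)
res = fk.run_pipeline(config)

print("independent (Fig.-2-style) effects, scaled to 1 SD:")
cols = ["exposure", "delta", "scaled_or", "scaled_ci_low", "scaled_ci_high"]
print(res.independent[cols].round(3).to_string(index=False))
truth = res.cohort.truth
print(f"generative truth: GLU {truth.true_or_1sd_glu:.2f}, TG {truth.true_or_1sd_tg:.2f}")

print("\n2x2 cells (reference = low GLU score & low TG score):")
tab = res.designs["2x2"]["table"]
print(tab[["cell", "n", "n_cases", "odds_ratio", "ci_low", "ci_high",
           "delta_glu", "delta_logtg"]].round(3).to_string(index=False))
gap = res.designs["2x2"]["additivity_gap"]
gap_se = res.designs["2x2"]["additivity_gap_se"]
print(f"\nlog-additivity gap (joint - sum of marginals): {gap:.3f} (SE {gap_se:.3f})")
# a gap within ~2 SE of zero supports the log-additive joint effect the
# factorial design is meant to demonstrate

het = res.designs["2x4_glu_binary"]["heterogeneity"]
print(f"2x4 heterogeneity of the binary-GLU OR across TG quartiles: "
      f"Q = {het['Q']:.2f} (df {het['df']}), p = {het['p']:.3f}")

strata = res.designs["2x4_glu_binary"]["strata"]
z, p = fk.interaction_z(
    (strata.loc[0, "log_or"], strata.loc[0, "se"]),
    (strata.loc[3, "log_or"], strata.loc[3, "se"]),
)
print(f"interaction z-test Q1 vs Q4 TG stratum: z = {z:.2f}, p = {p:.3f}")

print("\nobservational analogue (phenotype medians instead of GRS medians):")
print(res.observational[cols].round(3).to_string(index=False))
# the observational scaled ORs absorb the planted confounder; the factorial
# (GRS-based) estimates above stay near the generative truth
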