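"""Cross-check REML against PCGC regression on the same data.

PCGC regresses pairwise phenotype products on GRM entries and is
immune to the scale-conversion bias REML can incur on ascertained
binary traits; close agreement indicates the REML conversion is safe.
"""

import numpy as np

from liabherit import (
    GenoSimConfig,
    LiabilityContext,
    assign_liability_phenotypes,
    compute_grm,
    fit_pcgc,
    fit_reml,
    obs_to_liability,
    phenotype_frame,
    simulate_genotypes,
)

K = 0.2
cfg = GenoSimConfig(n_snps=1000, n_causal=100, h2_liab=0.4, prevalence_K=K, seed=3)
g = simulate_genotypes(cfg, n_samples=2000)
y = phenotype_frame(assign_liability_phenotypes(g, cfg))["status"].to_numpy()

grm = compute_grm(g)
ctx = LiabilityContext(K=K, P=float(y.mean()))

h2_greml = obs_to_liability(fit_reml(y.astype(float), None, [grm]).h2_obs_total, ctx)
pcgc = fit_pcgc(y, grm, ctx)

print(f"GREML  h2 (liability): {h2_greml:.3f}")
print(f"PCGC   h2 (liability): {pcgc.h2_liab:.3f} (jackknife SE {pcgc.se:.3f})")
print(f"difference:            {pcgc.h2_liab - h2_greml:+.3f}")
# Both estimators target the same liability-scale h2 (simulated truth
# 0.4); a difference well inside the jackknife SE indicates no
# conversion bias for this ascertainment level.
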