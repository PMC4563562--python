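"""Simulate an ascertained case-control GWAS panel under the liability model.

Draws genotypes and liabilities jointly from the population model and
keeps individuals until the case/control quotas are met, then writes
PLINK binary files plus a phenotype table.
"""

import numpy as np

from liabherit import GenoSimConfig, ascertain_case_control, phenotype_frame
from liabherit.plink import write_bed, write_phenotypes

cfg = GenoSimConfig(
    n_snps=2000,
    n_causal=200,
    h2_liab=0.4,
    prevalence_K=0.1,      # lifetime risk of the simulated disease
    n_cases=500,
    n_controls=1500,
    missing_rate=0.01,
    seed=1,
)
sample = ascertain_case_control(cfg)
f = phenotype_frame(sample.phenotypes)

write_bed(sample.genotypes, "sim")
write_phenotypes(
    "sim.pheno.tsv",
    sample.genotypes.sample_ids,
    f["status"],
    f["subtype"],
)

print(f"panel: {sample.genotypes.n_samples} samples x {sample.genotypes.n_snps} SNPs")
print(f"case fraction P = {sample.P:.3f} vs lifetime risk K = {sample.K}")
print(f"mean genetic value, cases:    {f.loc[f.status == 1, 'genetic_value'].mean():+.3f}")
print(f"mean genetic value, controls: {f.loc[f.status == 0, 'genetic_value'].mean():+.3f}")
# Cases are ascertained from the upper liability tail, so their mean
# genetic value exceeds the controls'; P >> K is what the liability
# transformation later corrects for.
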