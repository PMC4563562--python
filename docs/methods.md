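# Methods

## Model

All estimators in this package share one generative model. An
individual's disease status is the exceedance of a latent liability
over a fixed threshold: `y = 1{l > t}`, `t = Φ⁻¹(1−K)` for lifetime
risk `K`, with `l = g + (fixed effects) + e` where the additive
genetic value `g` has variance `h²` (narrow-sense heritability) and
the residual `e ~ N(0, 1−h²)` is independent, so `l` has unit variance
in the base population. Non-additive variance (dominance, epistasis,
gene-environment interaction) is deliberately outside the model; all
heritabilities here are narrow-sense.

## Genomic track

**GRM.** For SNP `i` with sample allele frequency `p̂_i`, the
off-diagonal relationship of samples `j, k` is the average of
`(x_ij − 2p̂_i)(x_ik − 2p̂_i)/(2p̂_i(1−p̂_i))` over SNPs non-missing in
both samples; each pair keeps its own SNP count, which keeps entries
unbiased when genotypes are missing completely at random. The default
diagonal uses the estimator
`1 + mean[(x² − (1+2p̂)x + 2p̂²)/(2p̂(1−p̂))]`, which corrects the
`O(1/n)` bias of the plain cross-product on the diagonal; the plain
form is available via `diagonal="crossproduct"` (and is the exactly
positive-semidefinite one). Allele frequencies come from the pooled
analysis sample. Sample-frequency centring makes each SNP's
standardized scores sum to zero, so off-diagonals of an unrelated
panel average `−1/(n−1)`, not 0 — relevant when interpreting very
small relationship estimates.

**AI-REML.** `fit_reml` maximizes the restricted likelihood of
`y ~ N(Xβ, Σ_c σ²_c A_c + σ²_e I)` by average-information updates. The
first step is always one EM update (robust far from the optimum);
subsequent AI steps are step-halved if they would decrease the
restricted log-likelihood, with a damped EM fallback; components are
constrained to a floor of `1e−8 ×` the phenotypic variance, and
components pinned at the floor whose score points further down are
held fixed within an iteration (active-set update). Convergence is
declared when the log-likelihood changes by less than `1e−6`
(configurable); non-convergence is a flagged result, not an
exception. Standard errors come from the inverse AI matrix; fractions
`h² = σ²_c / Σσ²` get delta-method SEs; confidence intervals are Wald
`±1.96 SE` on each scale. An AI matrix with condition number above
`1e10` marks the fit non-identifiable (e.g. an identity "GRM", which
is confounded with the residual).

With a single GRM the model is rotated into the GRM eigenbasis, where
the covariance is diagonal and each iteration costs `O(n p²)` after
one `O(n³)` eigendecomposition; with several GRMs a dense Cholesky
path is used. Both paths run the same update rule and agree with the
textbook dense evaluation of the restricted likelihood to ~1e−10
(tested), and AI and pure-EM iterations reach the same optimum on
small instances (tested on 50 seeds).

**Per-chromosome and per-SNP partitioning.** `fit_joint_chromosomes`
fits one component per chromosome simultaneously, and also reports the
single pooled-GRM estimate: the per-component sum and the whole-set
estimate partition noise differently and need not agree, so both are
reported explicitly rather than forced. Per-SNP attribution follows
the covariate-difference procedure: the joint model is fitted with and
without the SNP's dosage in the fixed effects, and the SNP is credited
with the drop in its chromosome's variance fraction. A SNP already
(collinearly) present in the design contributes zero by construction.

**Case-control phenotypes** enter REML as 0/1 values with an
intercept-only default design (no principal components; the synthetic
panels have no population structure, and the genomic-control
`λ`/`λ₁₀₀₀` statistics are computed so the assumption can be checked).
Observed-scale estimates transform to the liability scale by
`h²_liab = h²_obs · K²(1−K)²/(z²P(1−P))` — the lifetime risk `K`, not
the sample prevalence, sets the threshold; `P` is the realized case
fraction. SEs transform by the same factor.

**PCGC.** Standardized phenotype products `y*_j y*_k`,
`y* = (y−P)/√(P(1−P))`, are regressed through the origin on GRM
off-diagonals; the slope transforms by the same ascertainment
constant. The implementation is covariate-free (the cross-check the
package needs); the standard error is a delete-one-sample jackknife,
chosen for being assumption-light. The two estimators agree on
simulated data at moderate ascertainment (tested, 10 seeds).

## Quality control

SNP filters: MAF < 0.01; call rate < 0.95 computed separately within
cases and within controls (failing either removes the SNP); call rate
< 0.99 for SNPs with MAF in [0.01, 0.05]; Hardy-Weinberg `P < 0.05`.
The HWE test is a 1-df goodness-of-fit chi-square without continuity
correction, computed in controls only (the conventional GWAS choice,
since cases can deviate through real association); a conditional exact
test is available behind `hwe_exact=True`. Sample filters: call rate
< 0.99 and autosomal heterozygosity beyond 3 SD of the sample mean.
Ancestry-based exclusion is out of scope (it requires external
reference panels). The association statistic feeding the inflation
factor is the Cochran-Armitage trend test (1 df);
`λ = median(χ²)/0.4549`, `λ₁₀₀₀ = 1 + (λ−1)(1/n_ca + 1/n_co)/(2/1000)`.

## Population track

**NRM.** The numerator relationship matrix is built by the tabular
Henderson recursion after a topological sort (parents before
offspring); inbreeding is `F_i = A_ii − 1`. Its sparse inverse is
assembled directly from Henderson's rules with exact parental
inbreeding in the Mendelian-sampling variance. The recursion is
validated against gene-dropping Monte Carlo kinship (20,000 drops,
200-member random pedigree) and hand-computed cases.

**Gibbs sampler.** The probit animal model
`l = Xβ + u + e`, `u ~ N(0, A σ²_a)`, `e ~ N(0, I)` is fitted by data
augmentation: truncated-normal draws for `l` (side set by `y`,
threshold fixed at 0 with the intercept absorbing it), Gaussian draws
for `β` (flat prior), single-site updates for `u` over the sparse
`A⁻¹`, and a scaled-inverse-chi-square full conditional for `σ²_a`.
The residual variance is fixed at 1 — the threshold-model residual is
not identifiable — so `h² = σ²_a/(σ²_a + 1)` per retained round, and
the simulator generates data under this same convention, which makes
recovery tests internally consistent. Any different heritability
denominator convention used by other animal-model software is a
declared difference, not emulated. The prior on `σ²_a` is
scaled-inverse-chi-square with default `df = 1, scale = 1`
(configurable); note this default is heavy-tailed and implies a prior
mean for `h²` of ~0.66, so with weakly informative data (rare disease,
few affected relatives) the posterior mean sits visibly above a
simulation truth of 0.5 — a prior-dominance effect, not a sampler
defect (the sampler's full-conditional wiring is validated by a
prior-predictive Kolmogorov-Smirnov check, and the truncated-normal
kernel against closed-form truncated moments). Default chain settings
are registry-scale (1.1M rounds, 100k burn-in, thinning 1,000 → 1,000
retained samples); tests and examples scale these down. The inner loop
is compiled (numba) and seeds numba's RNG, so a fixed seed yields a
bit-identical chain. Summaries report the posterior mean, quantile
95% credible interval, autocorrelation-based effective sample size,
and a Geweke z-score.

**Cohort splits** refit the model with phenotype records restricted to
one era label while keeping the full pedigree for relationships, and
report whether the two credible intervals overlap.

## Recurrence risk

`sibling_rr` integrates the bivariate-normal tail
`P(l₂ > t | l₁ > t)` with correlation `r = a·h²` by outer adaptive
quadrature over the proband liability and an inner normal CDF,
demanding relative error below 1e−6; it matches scipy's bivariate CDF
oracle to that accuracy and is strictly increasing in `h²` and `a`.
The excess familial share uses the definition
`(λ_genetic − 1)/(λ_observed − 1)` and is labelled as such in output,
because alternative decompositions of familial risk exist and give
different shares.

## Synthetic data

The genotype generator draws allele frequencies uniformly on a MAF
window, genotypes in Hardy-Weinberg proportions at independent loci
(no linkage disequilibrium, no X chromosome), and missingness
completely at random. Causal effects are drawn spherically and
rescaled so the genetic variance equals the target `h²` exactly, which
pins realized heritability at its nominal value — convenient for
recovery tests, and the main way the generator is *less* variable than
real genetic architectures. Ascertainment is by rejection sampling of
complete individuals (genotype + liability) until case/control quotas
fill, keeping the genotype-liability coupling exact; the expected draw
count is checked against a budget up front, so tests use lifetime
risks ≥ 0.05 rather than rare-disease values. The pedigree generator
grows each family from a founder couple, with `1 + Poisson(mean − 1)`
children per couple and one child per couple marrying a new unrelated
founder in non-final generations; genetic values follow the Mendelian
recursion `a = (a_f + a_m)/2 + N(0, h²/2 · (1 − (F_f + F_m)/2))`.
Fixed-effect covariates are standard normal per individual with
user-specified effect sizes. Because the generators satisfy the
estimators' assumptions exactly, passing recovery tests demonstrates
correctness of the estimation machinery, not robustness to LD,
stratification, non-random missingness, assortative mating, or shared
family environment — none of which are simulated.

## Problem sizes and numerical choices

Recovery tests run at desk scale chosen to finish on one CPU: GREML
recovery at `n = 2,000` samples × `m = 1,000` SNPs × 10 seeds;
PCGC-GREML concordance at the same size with `P = K = 0.2`; pedigree
recovery at 1,000 two-generation families (mean sibship 3, ~5,000
individuals) with a 110,000-round chain. File formats follow PLINK
(text and SNP-major binary v1) and GCTA GRM conventions
(lower-triangle float32 binary and gzipped-text dialects), written and
read by the package itself. Degenerate inputs fail loudly:
monomorphic SNP subsets, constant phenotypes, rank-deficient designs,
empty strata, cyclic pedigrees, truncated binary files.

## Known limitations

- PCGC is covariate-free; covariate-adjusted PCGC with per-individual
  thresholds is not implemented.
- No LD-aware or MAF-stratified GRMs; no dominance components; no
  bivariate or GxE REML; no BLUP prediction.
- The Gibbs sampler supports a single additive random effect; no
  maternal, litter, or multi-trait models.
- Liability-scale SEs use the linear (delta) transform of
  observed-scale SEs; no resampling-based intervals for REML.
- The animal-model threshold is fixed at 0 with a free intercept;
  ordinal responses with more than two categories are not supported.
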