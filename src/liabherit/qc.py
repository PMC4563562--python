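"""SNP and sample quality control for case-control genotype panels.

Filters follow standard GWAS practice for a two-array case-control
design: per-SNP minor-allele-frequency, group-wise call-rate (with a
stricter rate for low-MAF SNPs), and Hardy-Weinberg filters; per-sample
call-rate and autosomal-heterozygosity outlier filters; and
genomic-control inflation statistics (lambda and its 1,000/1,000
rescaling) from one-degree-of-freedom association tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError
from .genotypes import GenotypeMatrix

#: Median of the 1-df chi-square distribution.
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass
class QcThresholds:
    """SNP- and sample-level filter thresholds.

    A SNP is dropped when MAF < ``maf_min``, call rate < ``callrate_min``
    in cases or in controls, MAF in [maf_min, lowmaf_cut] with call rate
    < ``callrate_min_lowmaf``, or a Hardy-Weinberg test P below
    ``hwe_p_min``. Samples are dropped on call rate <
    ``sample_callrate_min`` or heterozygosity beyond ``het_sd_limit``
    SDs of the sample mean.
    """

    maf_min: float = 0.01
    callrate_min: float = 0.95
    callrate_min_lowmaf: float = 0.99
    lowmaf_cut: float = 0.05
    hwe_p_min: float = 0.05
    sample_callrate_min: float = 0.99
    het_sd_limit: float = 3.0


@dataclass
class AssocStats:
    """Per-SNP 1-df association chi-squares with the design's group sizes."""

    chi2: np.ndarray
    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        self.chi2 = np.asarray(self.chi2, dtype=float)
        if self.chi2.size == 0:
            raise InvalidInputError("need at least one chi-square value")
        if np.any(self.chi2 < 0):
            raise InvalidInputError("chi-square values must be non-negative")


# ---------------------------------------------------------------------------
# Hardy-Weinberg tests
# ---------------------------------------------------------------------------


def hwe_chisq_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> tuple[float, float]:
    """1-df goodness-of-fit chi-square against Hardy-Weinberg proportions.

    Expected counts use the sample allele frequency; no continuity
    correction. Returns ``(chi2, p)``; monomorphic tables give (0, 1).
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 0.0, 1.0
    p = (2 * n_hom_alt + n_het) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 0.0, 1.0
    exp = np.array([n * q * q, 2 * n * p * q, n * p * p])
    obs = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return chi2, float(stats.chi2.sf(chi2, 1))


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test (sum of probabilities <= observed).

    Conditional distribution of the heterozygote count given allele
    counts; the PLINK-style two-sided exact P.
    """
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0 or n_rare == 0:
        return 1.0
    # probabilities over all heterozygote counts with the same parity
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    logp = np.zeros(hets.size)
    from scipy.special import gammaln

    for k, h in enumerate(hets):
        rare_hom = (n_rare - h) // 2
        com_hom = n - rare_hom - h
        logp[k] = (
            h * np.log(2)
            + gammaln(n + 1)
            - gammaln(rare_hom + 1)
            - gammaln(h + 1)
            - gammaln(com_hom + 1)
            - (gammaln(2 * n + 1) - gammaln(n_rare + 1) - gammaln(2 * n - n_rare + 1))
        )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs_p = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= obs_p * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# SNP and sample filters
# ---------------------------------------------------------------------------


def _genotype_counts(dos: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return (
        np.sum(dos == 0, axis=0),
        np.sum(dos == 1, axis=0),
        np.sum(dos == 2, axis=0),
    )


def filter_snps(
    G: GenotypeMatrix,
    status: np.ndarray,
    thr: QcThresholds | None = None,
    hwe_exact: bool = False,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the SNP filters; returns the retained matrix and a decision log.

    MAF is computed on non-missing calls pooled over cases and
    controls; call rates separately within cases and within controls
    (failing either removes the SNP); the Hardy-Weinberg test uses
    controls only. The log records the first rule that fired per SNP.
    """
    if G.n_snps == 0 or G.n_samples == 0:
        raise InvalidInputError("empty genotype matrix")
    thr = thr or QcThresholds()
    status = np.asarray(status).astype(int)
    if status.size != G.n_samples:
        raise InvalidInputError("status vector not aligned to samples")

    dos = G.dosages
    is_case = status == 1
    nonmiss = dos >= 0

    freqs = G.allele_freqs()
    maf = np.minimum(freqs, 1.0 - freqs)
    maf = np.where(np.isnan(maf), 0.0, maf)

    def callrate(mask: np.ndarray) -> np.ndarray:
        if mask.sum() == 0:
            return np.ones(G.n_snps)
        return nonmiss[mask].mean(axis=0)

    cr_case = callrate(is_case)
    cr_ctrl = callrate(~is_case)

    ctrl = dos[~is_case] if (~is_case).any() else dos
    c0, c1, c2 = _genotype_counts(ctrl)
    hwe_p = np.ones(G.n_snps)
    for i in range(G.n_snps):
        if hwe_exact:
            hwe_p[i] = hwe_exact_p(int(c0[i]), int(c1[i]), int(c2[i]))
        else:
            hwe_p[i] = hwe_chisq_p(int(c0[i]), int(c1[i]), int(c2[i]))[1]

    rule = np.full(G.n_snps, "", dtype=object)
    value = np.full(G.n_snps, np.nan)
    low_cr = np.minimum(cr_case, cr_ctrl)
    checks = [
        ("maf", maf < thr.maf_min, maf),
        ("callrate", low_cr < thr.callrate_min, low_cr),
        (
            "lowmaf_callrate",
            (maf >= thr.maf_min)
            & (maf <= thr.lowmaf_cut)
            & (low_cr < thr.callrate_min_lowmaf),
            low_cr,
        ),
        ("hwe", hwe_p < thr.hwe_p_min, hwe_p),
    ]
    for name, fired, val in checks:
        new = fired & (rule == "")
        rule[new] = name
        value[new] = val[new]

    keep = rule == ""
    log = pd.DataFrame(
        {
            "snp_id": G.snps["snp_id"],
            "kept": keep,
            "rule_fired": rule,
            "value": value,
            "maf": maf,
            "callrate_cases": cr_case,
            "callrate_controls": cr_ctrl,
            "hwe_p": hwe_p,
        }
    )
    return G.select_snps(keep), log


def filter_samples(
    G: GenotypeMatrix, thr: QcThresholds | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove samples with low call rate or outlying heterozygosity.

    Heterozygosity is the fraction of non-missing autosomal calls that
    are heterozygous; outliers lie more than ``het_sd_limit`` SDs from
    the across-sample mean.
    """
    if G.n_samples < 2:
        raise InvalidInputError("need at least 2 samples")
    thr = thr or QcThresholds()
    nonmiss = G.dosages >= 0
    n_called = nonmiss.sum(axis=1)
    callrate = n_called / G.n_snps
    with np.errstate(invalid="ignore"):
        het = np.where(n_called > 0, (G.dosages == 1).sum(axis=1) / n_called, 0.0)
    mu, sd = het.mean(), het.std()

    rule = np.full(G.n_samples, "", dtype=object)
    low_cr = callrate < thr.sample_callrate_min
    rule[low_cr] = "callrate"
    if np.isfinite(thr.het_sd_limit) and sd > 0:
        out = (np.abs(het - mu) > thr.het_sd_limit * sd) & (rule == "")
        rule[out] = "heterozygosity"
    keep = rule == ""
    if not keep.any():
        raise InvalidInputError("sample QC removed every sample")
    log = pd.DataFrame(
        {
            "sample_id": G.sample_ids,
            "kept": keep,
            "rule_fired": rule,
            "callrate": callrate,
            "heterozygosity": het,
        }
    )
    return G.select_samples(keep), log


# ---------------------------------------------------------------------------
# association tests and genomic control
# ---------------------------------------------------------------------------


def trend_test(G: GenotypeMatrix, status: np.ndarray) -> AssocStats:
    """Cochran-Armitage trend chi-square (1 df) per SNP.

    Additive scores (0, 1, 2); missing calls are excluded per SNP.
    """
    status = np.asarray(status).astype(int)
    dos = G.dosages_float()
    y = status.astype(float)
    chi2 = np.zeros(G.n_snps)
    for i in range(G.n_snps):
        x = dos[:, i]
        ok = ~np.isnan(x)
        xi, yi = x[ok], y[ok]
        n = xi.size
        if n == 0 or xi.std() == 0 or yi.std() == 0:
            continue
        r = np.corrcoef(xi, yi)[0, 1]
        chi2[i] = n * r * r
    return AssocStats(chi2, int(status.sum()), int((status == 0).sum()))


def inflation_lambda(assoc: AssocStats) -> tuple[float, float]:
    """Genomic-control inflation factor and its 1,000/1,000 rescaling.

    ``lambda = median(chi2) / 0.4549...`` (the 1-df chi-square median);
    ``lambda_1000 = 1 + (lambda - 1) * (1/n_cases + 1/n_controls) / (2/1000)``.
    """
    if assoc.n_cases <= 0 or assoc.n_controls <= 0:
        raise InvalidInputError("sample counts must be positive")
    lam = float(np.median(assoc.chi2) / CHI2_1DF_MEDIAN)
    lam_1000 = 1.0 + (lam - 1.0) * (1.0 / assoc.n_cases + 1.0 / assoc.n_controls) / (
        2.0 / 1000.0
    )
    return lam, lam_1000
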