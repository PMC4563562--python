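"""Seeded generators for case-control GWAS and pedigree datasets under
the additive liability-threshold model.

Both tracks share one generative story: each individual carries a
standard-normal liability ``l = g + (fixed effects) + e`` with additive
genetic value ``g`` of variance ``h2_liab`` and independent residual of
variance ``1 - h2_liab``; disease status is ``l > t`` where ``t =
Phi^-1(1 - K)`` for lifetime risk K. The genomic generator realizes
``g`` from independent Hardy-Weinberg SNPs; the pedigree generator
transmits it through parent-offspring Mendelian sampling. These are the
stand-ins for the registry and GWAS data the analyses expect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidConfigError, ResourceBudgetError
from .genotypes import MISSING, GenotypeMatrix
from .pedigree import Pedigree

UNKNOWN_P = "0"


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass
class GenoSimConfig:
    """Settings for the case-control genotype simulator.

    Defaults mirror the study conditions this generator stands in for:
    922 cases / 4,842 controls at lifetime risk K = 0.005 (tests use
    desk-scale overrides, in particular a larger K so ascertainment
    rejection sampling stays cheap).
    """

    n_snps: int = 1000
    maf_low: float = 0.05
    maf_high: float = 0.5
    n_causal: int = 100
    h2_liab: float = 0.374
    prevalence_K: float = 0.005
    n_cases: int = 922
    n_controls: int = 4842
    missing_rate: float = 0.0
    n_chromosomes: int = 22
    subtype_split: float = 0.5
    seed: int = 0
    max_draws: int = 2_000_000

    def __post_init__(self) -> None:
        if self.n_snps <= 0:
            raise InvalidConfigError("n_snps must be positive")
        if not 0 < self.maf_low <= self.maf_high <= 0.5:
            raise InvalidConfigError("need 0 < maf_low <= maf_high <= 0.5")
        if not 0 <= self.n_causal <= self.n_snps:
            raise InvalidConfigError("n_causal must be in [0, n_snps]")
        if not 0.0 <= self.h2_liab <= 1.0:
            raise InvalidConfigError("h2_liab must be in [0, 1]")
        if not 0.0 < self.prevalence_K < 1.0:
            raise InvalidConfigError("prevalence_K must be in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise InvalidConfigError("missing_rate must be in [0, 1)")
        if self.n_cases < 0 or self.n_controls < 0:
            raise InvalidConfigError("sample counts must be non-negative")


@dataclass
class PedSimConfig:
    """Settings for the multi-generation family simulator.

    Families start from an unrelated founder couple; each couple has
    ``1 + Poisson(sibship_mean - 1)`` children, and in non-final
    generations one child per couple marries a new unrelated founder
    and continues the line. ``covariate_effects`` adds fixed effects to
    the liability (each covariate is standard normal per individual).
    """

    n_families: int = 1000
    n_generations: int = 2
    sibship_mean: float = 2.5
    h2_liab: float = 0.5
    prevalence_K: float = 0.05
    covariate_effects: Sequence[tuple[str, float]] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families <= 0:
            raise InvalidConfigError("n_families must be positive")
        if not 2 <= self.n_generations <= 5:
            raise InvalidConfigError("n_generations must be in [2, 5]")
        if self.sibship_mean < 1.0:
            raise InvalidConfigError("sibship_mean must be >= 1")
        if not 0.0 <= self.h2_liab <= 1.0:
            raise InvalidConfigError("h2_liab must be in [0, 1]")
        if not 0.0 < self.prevalence_K < 1.0:
            raise InvalidConfigError("prevalence_K must be in (0, 1)")


@dataclass
class LiabilityPhenotype:
    """One individual's latent liability and observed status."""

    liability: float
    genetic_value: float
    status: int
    subtype_label: str | None = None


def phenotype_frame(phenos: Sequence[LiabilityPhenotype]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "liability": [p.liability for p in phenos],
            "genetic_value": [p.genetic_value for p in phenos],
            "status": [p.status for p in phenos],
            "subtype": [p.subtype_label for p in phenos],
        }
    )


# ---------------------------------------------------------------------------
# genotype track
# ---------------------------------------------------------------------------


def _draw_freqs(config: GenoSimConfig, rng: np.random.Generator) -> np.ndarray:
    return rng.uniform(config.maf_low, config.maf_high, size=config.n_snps)


def _snp_table(config: GenoSimConfig) -> pd.DataFrame:
    m = config.n_snps
    chroms = (np.arange(m) % config.n_chromosomes) + 1
    return pd.DataFrame(
        {
            "snp_id": [f"snp{i + 1}" for i in range(m)],
            "chrom": chroms,
            "pos": np.arange(m) * 1000 + 1,
            "a1": "A",
            "a2": "G",
        }
    )


def _draw_genotypes(
    freqs: np.ndarray, n: int, missing_rate: float, rng: np.random.Generator
) -> np.ndarray:
    g = rng.binomial(2, freqs, size=(n, freqs.size)).astype(np.int8)
    if missing_rate > 0:
        g[rng.random((n, freqs.size)) < missing_rate] = MISSING
    return g


def simulate_genotypes(config: GenoSimConfig, n_samples: int | None = None) -> GenotypeMatrix:
    """Population genotypes: independent SNPs in Hardy-Weinberg proportions.

    Allele frequencies are drawn uniformly on [maf_low, maf_high];
    chromosome labels are assigned round-robin over
    ``config.n_chromosomes``. Missing calls are inserted completely at
    random at ``missing_rate``.
    """
    n = (config.n_cases + config.n_controls) if n_samples is None else n_samples
    if n <= 0:
        raise InvalidConfigError("sample count must be positive")
    rng = np.random.default_rng(config.seed)
    freqs = _draw_freqs(config, rng)
    g = _draw_genotypes(freqs, n, config.missing_rate, rng)
    gm = GenotypeMatrix(g, _snp_table(config))
    gm.snps["sim_maf"] = freqs  # drawn truth kept for oracle checks
    return gm


def _causal_model(config: GenoSimConfig, rng: np.random.Generator):
    """Seeded causal-SNP indices and effect sizes on standardized dosages.

    Effects are drawn spherically and rescaled so the total genetic
    variance equals ``h2_liab`` exactly (sum of squared standardized
    effects = h2), which pins the realized heritability at its target.
    """
    idx = rng.choice(config.n_snps, size=config.n_causal, replace=False)
    idx.sort()
    raw = rng.standard_normal(config.n_causal)
    norm = np.linalg.norm(raw)
    beta = raw / norm * np.sqrt(config.h2_liab) if norm > 0 else raw
    return idx, beta


def _genetic_values(
    g: np.ndarray, freqs: np.ndarray, idx: np.ndarray, beta: np.ndarray
) -> np.ndarray:
    """Additive genetic values from standardized causal dosages.

    Standardization uses the generating allele frequencies, so each
    causal column has unit variance in the population and
    var(g) = sum(beta^2) = h2 by construction. Missing calls are
    mean-imputed (dosage 2p), i.e. contribute zero after centring.
    """
    if idx.size == 0:
        return np.zeros(g.shape[0])
    sub = g[:, idx].astype(np.float64)
    p = freqs[idx]
    miss = sub < 0
    if miss.any():
        sub[miss] = np.take(2.0 * p, np.nonzero(miss)[1])
    z = (sub - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    return z @ beta


def _finish_phenotypes(
    gval: np.ndarray, config: GenoSimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    resid_sd = np.sqrt(max(0.0, 1.0 - config.h2_liab))
    liab = gval + rng.standard_normal(gval.size) * resid_sd
    t = stats.norm.ppf(1.0 - config.prevalence_K)
    status = (liab > t).astype(int)
    return liab, status, t


def _subtype_labels(
    status: np.ndarray, split: float, rng: np.random.Generator
) -> list[str | None]:
    labels: list[str | None] = [None] * status.size
    for i in np.flatnonzero(status == 1):
        labels[i] = "subtype_a" if rng.random() < split else "subtype_b"
    return labels


def assign_liability_phenotypes(
    G: GenotypeMatrix, config: GenoSimConfig
) -> list[LiabilityPhenotype]:
    """Liability phenotypes for an existing genotype matrix.

    The causal model (SNP subset and effects) is re-derived from
    ``config.seed``, so the same config applied to its own genotypes
    reproduces the generative coupling. Requires the generator-truth
    allele frequencies stored by ``simulate_genotypes``.
    """
    rng = np.random.default_rng(config.seed + 1)
    idx, beta = _causal_model(config, rng)
    freqs = (
        G.snps["sim_maf"].to_numpy()
        if "sim_maf" in G.snps.columns
        else G.allele_freqs()
    )
    gval = _genetic_values(G.dosages, freqs, idx, beta)
    liab, status, _ = _finish_phenotypes(gval, config, rng)
    labels = _subtype_labels(status, config.subtype_split, rng)
    return [
        LiabilityPhenotype(float(liab[i]), float(gval[i]), int(status[i]), labels[i])
        for i in range(liab.size)
    ]


class CaseControlSample(NamedTuple):
    """Ascertained dataset plus the quantities the liability transform needs."""

    genotypes: GenotypeMatrix
    phenotypes: list[LiabilityPhenotype]
    P: float
    K: float


def ascertain_case_control(config: GenoSimConfig) -> CaseControlSample:
    """Rejection-sample a case-control panel from the population model.

    Individuals (genotypes and liabilities jointly) are simulated in
    batches from the population model and kept until the case and
    control quotas are filled, which reproduces case ascertainment
    exactly rather than approximating it. The expected number of draws
    is checked against ``config.max_draws`` up front; very small K
    needs a larger budget (tests use K >= 0.05).
    """
    K = config.prevalence_K
    expected = config.n_controls / (1 - K) + (config.n_cases / K if config.n_cases else 0)
    if expected > config.max_draws:
        raise ResourceBudgetError(
            f"ascertainment expects ~{expected:.0f} population draws "
            f"(> max_draws={config.max_draws}); raise max_draws or use a larger K"
        )
    rng = np.random.default_rng(config.seed)
    freqs = _draw_freqs(config, rng)
    idx, beta = _causal_model(config, rng)

    kept_g: list[np.ndarray] = []
    kept: list[tuple[float, float, int]] = []
    n_case = n_ctrl = 0
    drawn = 0
    batch = max(256, min(8192, int(expected / 4) + 1))
    while n_case < config.n_cases or n_ctrl < config.n_controls:
        if drawn > 4 * config.max_draws:
            raise ResourceBudgetError("ascertainment draw budget exhausted")
        g = _draw_genotypes(freqs, batch, config.missing_rate, rng)
        gval = _genetic_values(g, freqs, idx, beta)
        liab, status, _ = _finish_phenotypes(gval, config, rng)
        drawn += batch
        for i in range(batch):
            if status[i] == 1 and n_case < config.n_cases:
                kept_g.append(g[i])
                kept.append((liab[i], gval[i], 1))
                n_case += 1
            elif status[i] == 0 and n_ctrl < config.n_controls:
                kept_g.append(g[i])
                kept.append((liab[i], gval[i], 0))
                n_ctrl += 1

    status_arr = np.array([k[2] for k in kept])
    rng_lab = np.random.default_rng(config.seed + 2)
    labels = _subtype_labels(status_arr, config.subtype_split, rng_lab)
    phenos = [
        LiabilityPhenotype(float(l), float(gv), int(s), labels[i])
        for i, (l, gv, s) in enumerate(kept)
    ]
    gm = GenotypeMatrix(np.vstack(kept_g) if kept_g else
                        np.zeros((0, config.n_snps), dtype=np.int8),
                        _snp_table(config))
    gm.snps["sim_maf"] = freqs
    n_total = config.n_cases + config.n_controls
    P = config.n_cases / n_total if n_total else 0.0
    return CaseControlSample(gm, phenos, P, K)


# ---------------------------------------------------------------------------
# pedigree track
# ---------------------------------------------------------------------------


def simulate_pedigree(
    config: PedSimConfig,
) -> tuple[Pedigree, list[LiabilityPhenotype], pd.DataFrame]:
    """Multi-generation families with additive liability transmission.

    Founders receive genetic values a ~ N(0, h2); offspring get the
    parental mean plus a Mendelian-sampling deviate of variance
    ``h2/2 * (1 - (F_f + F_m)/2)`` (F = 0 here: spouses are always new
    founders). Liability adds fixed-effect contributions and a
    N(0, 1 - h2) residual; status thresholds at Phi^-1(1 - K).
    """
    rng = np.random.default_rng(config.seed)
    h2 = config.h2_liab
    mend_sd = np.sqrt(h2 / 2.0) if h2 > 0 else 0.0
    rows = []  # id, father, mother, sex, family, generation
    avals = []

    def new_person(fam, gen, sex, father, mother, a):
        # father/mother: integer row index, or "0" for a founder
        rows.append([None, father, mother, sex, fam, gen])
        avals.append(a)
        return len(rows) - 1

    for fam in range(1, config.n_families + 1):
        # founding couple
        fa = new_person(fam, 1, 1, UNKNOWN_P, UNKNOWN_P, rng.normal(0, np.sqrt(h2)) if h2 > 0 else 0.0)
        mo = new_person(fam, 1, 2, UNKNOWN_P, UNKNOWN_P, rng.normal(0, np.sqrt(h2)) if h2 > 0 else 0.0)
        couples = [(fa, mo)]
        for gen in range(2, config.n_generations + 1):
            next_couples = []
            for f_i, m_i in couples:
                n_kids = 1 + rng.poisson(config.sibship_mean - 1.0)
                kids = []
                for _ in range(n_kids):
                    a = 0.5 * (avals[f_i] + avals[m_i]) + (
                        rng.normal(0, mend_sd) if h2 > 0 else 0.0
                    )
                    sex = 1 if rng.random() < 0.5 else 2
                    kids.append(new_person(fam, gen, sex, f_i, m_i, a))
                if gen < config.n_generations and kids:
                    heir = kids[int(rng.integers(len(kids)))]
                    heir_sex = rows[heir][3]
                    sp_sex = 2 if heir_sex == 1 else 1
                    spouse = new_person(
                        fam, gen, sp_sex, UNKNOWN_P, UNKNOWN_P,
                        rng.normal(0, np.sqrt(h2)) if h2 > 0 else 0.0,
                    )
                    pair = (heir, spouse) if heir_sex == 1 else (spouse, heir)
                    next_couples.append(pair)
            couples = next_couples

    n = len(rows)
    ids = [f"I{i + 1}" for i in range(n)]
    table = pd.DataFrame(
        {
            "id": ids,
            "father": [ids[r[1]] if isinstance(r[1], int) else "0" for r in rows],
            "mother": [ids[r[2]] if isinstance(r[2], int) else "0" for r in rows],
            "sex": [r[3] for r in rows],
            "family": [r[4] for r in rows],
            "generation": [r[5] for r in rows],
        }
    )
    ped = Pedigree(table)

    a = np.asarray(avals)
    covs = pd.DataFrame({"sample_id": ids, "sex": table["sex"].to_numpy()})
    fixed = np.zeros(n)
    for name, effect in config.covariate_effects:
        x = rng.standard_normal(n)
        covs[name] = x
        fixed += effect * x
    resid_sd = np.sqrt(max(0.0, 1.0 - h2))
    liab = a + fixed + rng.standard_normal(n) * resid_sd
    t = stats.norm.ppf(1.0 - config.prevalence_K)
    status = (liab > t).astype(int)
    phenos = [
        LiabilityPhenotype(float(liab[i]), float(a[i]), int(status[i])) for i in range(n)
    ]
    return ped, phenos, covs
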