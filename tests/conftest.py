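import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from liabherit import GenoSimConfig, GenotypeMatrix, Pedigree

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def small_config():
    return GenoSimConfig(
        n_snps=120,
        n_causal=30,
        maf_low=0.1,
        maf_high=0.5,
        h2_liab=0.4,
        prevalence_K=0.2,
        n_cases=60,
        n_controls=140,
        n_chromosomes=4,
        seed=11,
    )


def make_genotypes(dosages, chroms=None):
    """GenotypeMatrix from a raw dosage array (testing helper)."""
    dosages = np.asarray(dosages, dtype=np.int8)
    m = dosages.shape[1]
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(m)],
            "chrom": chroms if chroms is not None else [1] * m,
            "pos": np.arange(m) + 1,
            "a1": "A",
            "a2": "G",
        }
    )
    return GenotypeMatrix(dosages, snps)


def make_pedigree(rows):
    """Pedigree from (id, father, mother, sex) tuples."""
    t = pd.DataFrame(rows, columns=["id", "father", "mother", "sex"])
    return Pedigree(t)


@pytest.fixture
def trio():
    return make_pedigree(
        [("dad", "0", "0", 1), ("mum", "0", "0", 2), ("kid", "dad", "mum", 1)]
    )
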