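"""Small reference constants used by the reporting layer.

``GRCH37_CHROMOSOME_LENGTHS`` are the GRCh37/hg19 autosome lengths in
base pairs. The two published reference tables hold per-chromosome and
per-SNP fractions of phenotypic variance reported for a testicular
germ cell tumour case-control GWAS heritability partition; they are
convenient worked-example inputs for the partition-report utilities.
"""

from __future__ import annotations

import pandas as pd

#: GRCh37 autosome lengths (bp), chromosomes 1-22.
GRCH37_CHROMOSOME_LENGTHS: dict[int, int] = {
    1: 249250621, 2: 243199373, 3: 198022430, 4: 191154276,
    5: 180915260, 6: 171115067, 7: 159138663, 8: 146364022,
    9: 141213431, 10: 135534747, 11: 135006516, 12: 133851895,
    13: 115169878, 14: 107349540, 15: 102531392, 16: 90354753,
    17: 81195210, 18: 78077248, 19: 59128983, 20: 63025520,
    21: 48129895, 22: 51304566,
}

# Published per-chromosome fractions of phenotypic variance (with SEs)
# from a testicular germ cell tumour SNP-heritability partition; the
# published whole-autosome single-GRM total was 0.3736 +/- 0.0500.
_TGCT_CHROM_ROWS = [
    (1, 0.0422, 0.0150), (2, 0.0232, 0.0143), (3, 0.0506, 0.0140),
    (4, 0.0313, 0.0129), (5, 0.0017, 0.0122), (6, 0.0248, 0.0128),
    (7, 0.0178, 0.0116), (8, 0.0095, 0.0112), (9, 0.0200, 0.0115),
    (10, 0.0124, 0.0118), (11, 0.0192, 0.0111), (12, 0.0339, 0.0119),
    (13, 0.0058, 0.0095), (14, 0.0117, 0.0093), (15, 0.0150, 0.0091),
    (16, 0.0083, 0.0097), (17, 0.0188, 0.0093), (18, 0.0143, 0.0096),
    (19, 0.0050, 0.0080), (20, 0.0342, 0.0104), (21, 0.0033, 0.0062),
    (22, 0.0000, 0.0069),
]

#: Whole-autosome single-GRM observed total for the same partition.
TGCT_WHOLE_AUTOSOME_FRACTION = 0.3736
TGCT_WHOLE_AUTOSOME_SE = 0.0500

# Published per-SNP variance fractions for the 19 established TGCT
# risk loci (same study series); published collective total 0.0921.
_TGCT_SNP_ROWS = [
    ("rs2072499", "1q22", 0.0030, 0.0211),
    ("rs3790672", "1q24.1", 0.0013, 0.0211),
    ("rs10510452", "3p24.3", 0.0029, 0.0197),
    ("rs1510272", "3q25", 0.0048, 0.0197),
    ("rs17021463", "4q22.2", 0.0035, 0.0182),
    ("rs2720460", "4q24", 0.0046, 0.0181),
    ("rs4635969", "5p15", 0.0001, 0.0171),
    ("rs4624820", "5q31", 0.0017, 0.0172),
    ("rs3805663", "5q31.1", 0.0001, 0.0172),
    ("rs210138", "6p21", 0.0108, 0.0178),
    ("rs12699477", "7p22.3", 0.0049, 0.0162),
    ("rs7010162", "8q13.3", 0.0012, 0.0157),
    ("rs755383", "9p24", 0.0144, 0.0159),
    ("rs995030", "12q21", 0.0177, 0.0163),
    ("rs2900333", "12p13", 0.0028, 0.0167),
    ("rs8046148", "16q12.1", 0.0044, 0.0136),
    ("rs4888265", "16q22.3", 0.0013, 0.0136),
    ("rs9905704", "17q22", 0.0095, 0.0104),
    ("rs2839243", "21q22.3", 0.0033, 0.0090),
]


def tgct_chromosome_partition() -> pd.DataFrame:
    """Reference per-chromosome variance-fraction table (label, fraction, se)."""
    return pd.DataFrame(
        _TGCT_CHROM_ROWS, columns=["chrom", "fraction", "se"]
    )


def tgct_known_loci_partition() -> pd.DataFrame:
    """Reference per-SNP variance-fraction table for the 19 known risk loci."""
    return pd.DataFrame(
        _TGCT_SNP_ROWS, columns=["snp_id", "locus", "fraction", "se"]
    )
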