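"""In-memory genotype container used throughout the genomic track.

Genotypes are stored sample-major as ``int8`` minor-allele dosages
(0/1/2) with ``-1`` marking a missing call. SNP metadata lives in a
pandas DataFrame aligned column-wise with the dosage matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError

MISSING = np.int8(-1)

#: Required columns of the SNP metadata table.
SNP_COLUMNS = ("snp_id", "chrom", "pos", "a1", "a2")


@dataclass
class GenotypeMatrix:
    """n-samples x m-SNPs dosage matrix with SNP and sample metadata.

    Parameters
    ----------
    dosages
        ``(n, m)`` int8 array of minor-allele counts; ``-1`` is missing.
    snps
        DataFrame with columns ``snp_id, chrom, pos, a1, a2`` (one row
        per SNP, in column order of ``dosages``).
    sample_ids
        Length-n list of sample identifiers.
    """

    dosages: np.ndarray
    snps: pd.DataFrame
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise InvalidInputError("dosage matrix must be 2-D (samples x SNPs)")
        n, m = self.dosages.shape
        if len(self.snps) != m:
            raise InvalidInputError(
                f"SNP table has {len(self.snps)} rows but matrix has {m} SNPs"
            )
        missing_cols = set(SNP_COLUMNS) - set(self.snps.columns)
        if missing_cols:
            raise InvalidInputError(f"SNP table lacks columns: {sorted(missing_cols)}")
        if not self.sample_ids:
            self.sample_ids = [f"S{i + 1}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise InvalidInputError("sample_ids length does not match matrix rows")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def dosages_float(self) -> np.ndarray:
        """Dosages as float64 with missing calls mapped to NaN."""
        x = self.dosages.astype(np.float64)
        x[self.dosages == MISSING] = np.nan
        return x

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n, m)`` mask, True where the call is missing."""
        return self.dosages == MISSING

    def allele_freqs(self) -> np.ndarray:
        """Per-SNP sample frequency of the counted (a1) allele.

        Computed over non-missing calls pooled across all samples;
        NaN for SNPs with no calls.
        """
        x = self.dosages_float()
        with np.errstate(invalid="ignore"):
            return np.nanmean(x, axis=0) / 2.0

    def select_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to SNP columns ``index`` (bool or int)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.dosages[:, index],
            self.snps.iloc[index].reset_index(drop=True),
            list(self.sample_ids),
        )

    def select_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to sample rows ``index`` (bool or int)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.dosages[index, :],
            self.snps.copy(),
            [self.sample_ids[i] for i in index],
        )
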