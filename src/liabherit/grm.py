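"""Genetic relationship matrices from standardized SNP dosages.

Off-diagonals average ``(x_ij - 2p_i)(x_ik - 2p_i) / (2 p_i (1 - p_i))``
over SNPs non-missing in both samples; the default diagonal is the
GCTA form ``1 + mean[(x^2 - (1 + 2p) x + 2 p^2) / (2p(1-p))]``, with a
flag for the plain cross-product diagonal. Allele frequencies come
from the analysis sample; missing genotypes are handled by per-pair
renormalization, so each entry is a mean over its own SNP count.

Serialization supports the GCTA binary triplet (``.grm.bin`` /
``.grm.N.bin`` / ``.grm.id``: lower triangle, row-major, float32) and
the gzipped-text dialect (``.grm.gz``: i, j, count, value).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidInputError
from .genotypes import GenotypeMatrix


@dataclass
class Grm:
    """Symmetric realized-relationship matrix with provenance."""

    values: np.ndarray
    sample_ids: list[str]
    n_snps_pairwise: np.ndarray
    snp_subset: str = "all"

    @property
    def n(self) -> int:
        return self.values.shape[0]


def compute_grm(
    G: GenotypeMatrix,
    snp_subset: np.ndarray | None = None,
    diagonal: str = "gcta",
    subset_label: str | None = None,
) -> Grm:
    """GRM over the given SNP columns (default: all polymorphic SNPs).

    Parameters
    ----------
    snp_subset
        Bool mask or integer index of SNP columns; monomorphic SNPs
        (sample allele frequency 0 or 1) are dropped from the subset.
    diagonal
        ``"gcta"`` (default) or ``"crossproduct"``.
    """
    if G.n_samples < 2:
        raise InvalidInputError("need at least 2 samples")
    if diagonal not in ("gcta", "crossproduct"):
        raise InvalidInputError(f"unknown diagonal convention {diagonal!r}")

    if snp_subset is None:
        sub = G
        label = subset_label or "all"
    else:
        sub = G.select_snps(np.asarray(snp_subset))
        label = subset_label or "subset"

    x = sub.dosages_float()
    p = np.nanmean(x, axis=0) / 2.0
    poly = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise InvalidInputError("no polymorphic SNPs in subset")
    x = x[:, poly]
    p = p[poly]

    denom = 2.0 * p * (1.0 - p)
    z = (x - 2.0 * p) / np.sqrt(denom)
    miss = np.isnan(z)
    z0 = np.where(miss, 0.0, z)
    called = (~miss).astype(np.float64)

    counts = called @ called.T
    num = z0 @ z0.T
    with np.errstate(invalid="ignore", divide="ignore"):
        A = num / counts
    A[counts == 0] = 0.0

    n = sub.n_samples
    if diagonal == "gcta":
        x0 = np.where(miss, 0.0, x)
        # per-sample sum of (x^2 - (1+2p)x + 2p^2) / (2p(1-p)) over called SNPs
        term = (x0 * x0 - (1.0 + 2.0 * p) * x0 + 2.0 * p * p * called) / denom
        term[miss] = 0.0
        m_jj = called.sum(axis=1)
        diag = 1.0 + np.where(m_jj > 0, term.sum(axis=1) / m_jj, 0.0)
        A[np.diag_indices(n)] = diag

    return Grm(A, list(G.sample_ids), counts, label)


def per_chromosome_grms(G: GenotypeMatrix, diagonal: str = "gcta") -> list[Grm]:
    """One GRM per chromosome with at least one polymorphic SNP."""
    if "chrom" not in G.snps.columns:
        raise InvalidInputError("no chromosome labels in SNP table")
    out = []
    for chrom in pd.unique(G.snps["chrom"]):
        mask = (G.snps["chrom"] == chrom).to_numpy()
        try:
            out.append(
                compute_grm(G, mask, diagonal=diagonal, subset_label=f"chr{chrom}")
            )
        except InvalidInputError:
            continue  # chromosome with only monomorphic SNPs
    if not out:
        raise InvalidInputError("no chromosome produced a valid GRM")
    return out


# ---------------------------------------------------------------------------
# GCTA serialization
# ---------------------------------------------------------------------------


def _tri_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.tril_indices(n)


def write_grm(grm: Grm, prefix: str | Path, text: bool = False) -> None:
    """Write GCTA binary triplet, or the gzipped-text dialect if ``text``."""
    prefix = str(prefix)
    ids = pd.DataFrame({"fid": grm.sample_ids, "iid": grm.sample_ids})
    ids.to_csv(prefix + ".grm.id", sep="\t", header=False, index=False)
    rows, cols = _tri_indices(grm.n)
    vals = grm.values[rows, cols].astype(np.float32)
    counts = grm.n_snps_pairwise[rows, cols].astype(np.float32)
    if text:
        with gzip.open(prefix + ".grm.gz", "wt") as fh:
            for i, j, c, v in zip(rows + 1, cols + 1, counts, vals):
                fh.write(f"{i}\t{j}\t{c:.0f}\t{v:.6f}\n")
    else:
        vals.tofile(prefix + ".grm.bin")
        counts.tofile(prefix + ".grm.N.bin")


def read_grm(prefix: str | Path) -> Grm:
    """Read a GRM written by :func:`write_grm` (or GCTA)."""
    prefix = str(prefix)
    id_path = Path(prefix + ".grm.id")
    if not id_path.exists():
        raise FormatError(f"missing {id_path}")
    ids = pd.read_csv(id_path, sep=r"\s+", header=None)
    sample_ids = ids.iloc[:, 1].astype(str).tolist()
    n = len(sample_ids)
    n_pairs = n * (n + 1) // 2
    A = np.zeros((n, n))
    N = np.zeros((n, n))
    rows, cols = _tri_indices(n)

    gz_path = Path(prefix + ".grm.gz")
    bin_path = Path(prefix + ".grm.bin")
    if bin_path.exists():
        vals = np.fromfile(bin_path, dtype=np.float32)
        if vals.size != n_pairs:
            raise FormatError(
                f"{bin_path}: expected {n_pairs} float32 values, found {vals.size}"
            )
        nb_path = Path(prefix + ".grm.N.bin")
        counts = (
            np.fromfile(nb_path, dtype=np.float32)
            if nb_path.exists()
            else np.zeros(n_pairs, dtype=np.float32)
        )
        if counts.size not in (n_pairs, 1):
            raise FormatError(f"{nb_path}: count/id length mismatch")
        if counts.size == 1:
            counts = np.repeat(counts, n_pairs)
    elif gz_path.exists():
        tbl = pd.read_csv(gz_path, sep="\t", header=None)
        if len(tbl) != n_pairs:
            raise FormatError(f"{gz_path}: expected {n_pairs} rows, found {len(tbl)}")
        order = np.lexsort((tbl[1], tbl[0]))
        tbl = tbl.iloc[order]
        vals = tbl[3].to_numpy(dtype=np.float32)
        counts = tbl[2].to_numpy(dtype=np.float32)
    else:
        raise FormatError(f"no .grm.bin or .grm.gz found for prefix {prefix}")

    A[rows, cols] = vals
    A[cols, rows] = vals
    N[rows, cols] = counts
    N[cols, rows] = counts
    return Grm(A, sample_ids, N, "file")
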