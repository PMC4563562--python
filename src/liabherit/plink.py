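"""PLINK genotype file dialects and phenotype/covariate tables.

Supports the text pair (``.ped``/``.map``) and the binary triplet
(``.bed``/``.bim``/``.fam``, SNP-major v1: magic bytes 0x6c 0x1b 0x01,
two bits per genotype). Phenotype tables are TSV with columns
``sample_id, status`` plus optional ``subtype`` and covariates.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .genotypes import MISSING, GenotypeMatrix

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit codes, SNP-major: 00=hom a1 (dosage 2), 01=missing, 10=het, 11=hom a2
_CODE_TO_DOSAGE = np.array([2, -1, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}


# ---------------------------------------------------------------------------
# binary dialect
# ---------------------------------------------------------------------------


def write_bed(G: GenotypeMatrix, prefix: str | Path) -> None:
    """Write ``.bed`` (SNP-major v1) with companion ``.bim``/``.fam``."""
    prefix = str(prefix)
    n, m = G.n_samples, G.n_snps
    bim = pd.DataFrame(
        {
            "chrom": G.snps["chrom"],
            "snp_id": G.snps["snp_id"],
            "cm": 0,
            "pos": G.snps["pos"],
            "a1": G.snps["a1"],
            "a2": G.snps["a2"],
        }
    )
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": G.sample_ids,
            "iid": G.sample_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)

    codes = np.empty((m, n), dtype=np.uint8)
    dos = G.dosages.T  # SNP-major
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[dos == dosage] = code
    n_bytes = (n + 3) // 4
    packed = np.zeros((m, n_bytes), dtype=np.uint8)
    for offset in range(4):
        cols = np.arange(offset, n, 4)
        packed[:, : cols.size] |= codes[:, cols] << (2 * offset)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_bed(prefix: str | Path) -> GenotypeMatrix:
    """Read a ``.bed``/``.bim``/``.fam`` triplet."""
    prefix = str(prefix)
    bim = pd.read_csv(
        prefix + ".bim",
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None, dtype=str)
    sample_ids = fam.iloc[:, 1].tolist()
    n, m = len(sample_ids), len(bim)

    raw = Path(prefix + ".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic bytes (not SNP-major v1)")
    n_bytes = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != m * n_bytes:
        raise FormatError(
            f"{prefix}.bed: expected {m * n_bytes} data bytes, found {body.size}"
        )
    body = body.reshape(m, n_bytes)
    dos = np.empty((m, n), dtype=np.int8)
    for offset in range(4):
        cols = np.arange(offset, n, 4)
        codes = (body[:, : cols.size] >> (2 * offset)) & 0b11
        dos[:, cols] = _CODE_TO_DOSAGE[codes]
    snps = bim[["snp_id", "chrom", "pos", "a1", "a2"]].copy()
    return GenotypeMatrix(dos.T, snps, sample_ids)


# ---------------------------------------------------------------------------
# text dialect
# ---------------------------------------------------------------------------


def write_ped(G: GenotypeMatrix, prefix: str | Path) -> None:
    """Write the ``.ped``/``.map`` text pair (alleles space-separated)."""
    prefix = str(prefix)
    mp = G.snps[["chrom", "snp_id", "pos"]].copy()
    mp.insert(2, "cm", 0)
    mp.to_csv(prefix + ".map", sep="\t", header=False, index=False)
    a1 = G.snps["a1"].to_numpy()
    a2 = G.snps["a2"].to_numpy()
    with open(prefix + ".ped", "w") as fh:
        for i, sid in enumerate(G.sample_ids):
            fields = [sid, sid, "0", "0", "0", "-9"]
            row = G.dosages[i]
            for j in range(G.n_snps):
                d = row[j]
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 2:
                    fields += [a1[j], a1[j]]
                elif d == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a2[j], a2[j]]
            fh.write(" ".join(map(str, fields)) + "\n")


def read_ped(prefix: str | Path) -> GenotypeMatrix:
    """Read a ``.ped``/``.map`` pair; dosage counts the ``.map`` a1 allele.

    Allele labels are inferred per SNP from the data (first-seen allele
    is a1 unless only one allele occurs).
    """
    prefix = str(prefix)
    mp = pd.read_csv(
        prefix + ".map",
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos"],
        dtype={"snp_id": str},
    )
    m = len(mp)
    sample_ids = []
    rows = []
    alleles: list[dict[str, int]] = [dict() for _ in range(m)]
    raw_pairs = []
    with open(prefix + ".ped") as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise FormatError(
                    f"{prefix}.ped: row with {len(parts)} fields, expected {6 + 2 * m}"
                )
            sample_ids.append(parts[1])
            pairs = [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(m)]
            raw_pairs.append(pairs)
            for j, (x, y) in enumerate(pairs):
                for al in (x, y):
                    if al != "0":
                        alleles[j].setdefault(al, len(alleles[j]))
    a1 = [sorted(d, key=d.get)[0] if d else "A" for d in alleles]
    a2 = [
        sorted(d, key=d.get)[1] if len(d) > 1 else ("G" if a1[j] != "G" else "A")
        for j, d in enumerate(alleles)
    ]
    for pairs in raw_pairs:
        row = np.empty(m, dtype=np.int8)
        for j, (x, y) in enumerate(pairs):
            if x == "0" or y == "0":
                row[j] = MISSING
            else:
                row[j] = int(x == a1[j]) + int(y == a1[j])
        rows.append(row)
    snps = pd.DataFrame(
        {
            "snp_id": mp["snp_id"],
            "chrom": mp["chrom"],
            "pos": mp["pos"],
            "a1": a1,
            "a2": a2,
        }
    )
    return GenotypeMatrix(np.vstack(rows), snps, sample_ids)


# ---------------------------------------------------------------------------
# phenotype / covariate tables
# ---------------------------------------------------------------------------


def write_phenotypes(
    path: str | Path,
    sample_ids: list[str],
    status: np.ndarray,
    subtype=None,
    covariates: pd.DataFrame | None = None,
) -> None:
    """Phenotype TSV: sample_id, status (0/1), subtype, covariates."""
    out = pd.DataFrame({"sample_id": sample_ids, "status": np.asarray(status, int)})
    if subtype is not None:
        out["subtype"] = [s if s is not None else "" for s in subtype]
    if covariates is not None:
        cov = covariates.drop(columns=["sample_id"], errors="ignore")
        out = pd.concat([out, cov.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t")
    if "sample_id" not in t.columns or "status" not in t.columns:
        raise FormatError("phenotype TSV needs sample_id and status columns")
    t["sample_id"] = t["sample_id"].astype(str)
    return t
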