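"""PLINK bed/bim/fam and phenotype-table I/O.

Implements the PLINK 1 binary genotype codec (SNP-major .bed: magic bytes
0x6c 0x1b 0x01, then per SNP ceil(n/4) bytes of 2-bit codes 00=hom alt,
01=missing, 10=het, 11=hom ref counted as reference-allele copies 0/NA/1/2)
plus the .bim/.fam sidecars, and the TSV phenotype/covariate table used
throughout the pipeline (columns FID, IID, sex, phenotype, covariates...).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simgen import MISSING, GenotypeMatrix, GxsTruth, SexedCohort

# PLINK 1 2-bit codes: 00=hom A1, 01=missing, 10=het, 11=hom A2.
# We count copies of A1 (the reference allele), the PLINK additive coding.
_CODE_TO_COUNT = np.array([2, -9, 1, 0], dtype=np.int8)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])


class PlinkFormatError(ValueError):
    pass


def write_plink(geno: GenotypeMatrix, prefix: str | Path, sex: np.ndarray | None = None) -> None:
    """Write genotypes as PLINK ``prefix.bed/.bim/.fam`` (SNP-major).

    Chromosome/position fields in the .bim are synthetic (chromosome 1,
    positions 1..M, alleles A/B) but well formed.
    """
    prefix = Path(prefix)
    n, m = geno.n, geno.m

    fam = pd.DataFrame(
        {
            "fid": geno.ids,
            "iid": geno.ids,
            "father": 0,
            "mother": 0,
            "sex": sex if sex is not None else 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    bim = pd.DataFrame(
        {
            "chrom": 1,
            "snp": geno.snp_ids,
            "cm": 0,
            "pos": np.arange(1, m + 1),
            "a1": "A",  # reference (counted) allele
            "a2": "B",
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    codes = np.empty((n, m), dtype=np.uint8)
    counts = geno.counts
    codes[counts == 2] = 0
    codes[counts == MISSING] = 1
    codes[counts == 1] = 2
    codes[counts == 0] = 3
    n_bytes = (n + 3) // 4
    # pack per SNP, little-endian within each byte
    padded = np.zeros((4 * n_bytes, m), dtype=np.uint8)
    padded[:n] = codes
    b = (
        padded[0::4]
        | (padded[1::4] << 2)
        | (padded[2::4] << 4)
        | (padded[3::4] << 6)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(b.T.tobytes())  # SNP-major


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK 1 ``prefix.bed/.bim/.fam`` triplet."""
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"iid": str, "fid": str},
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"snp": str},
    )
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise PlinkFormatError(f"{prefix}.bed lacks the PLINK SNP-major magic")
    n_bytes = (n + 3) // 4
    body = raw[3:]
    if body.size != n_bytes * m:
        raise PlinkFormatError(
            f"{prefix}.bed payload has {body.size} bytes, expected {n_bytes * m}"
        )
    b = body.reshape(m, n_bytes)
    codes = np.empty((m, 4 * n_bytes), dtype=np.uint8)
    codes[:, 0::4] = b & 0b11
    codes[:, 1::4] = (b >> 2) & 0b11
    codes[:, 2::4] = (b >> 4) & 0b11
    codes[:, 3::4] = (b >> 6) & 0b11
    counts = _CODE_TO_COUNT[codes[:, :n]].T
    return GenotypeMatrix(
        ids=fam["iid"].to_numpy(dtype=object),
        snp_ids=bim["snp"].to_numpy(dtype=object),
        counts=counts,
    )


# ---------------------------------------------------------------------------
# phenotype / covariate tables


def write_phenotypes(cohort: SexedCohort, path: str | Path) -> None:
    """Write a TSV with columns FID, IID, sex, phenotype, then covariates."""
    df = pd.DataFrame({"FID": cohort.ids, "IID": cohort.ids, "sex": cohort.sex})
    df["phenotype"] = cohort.y
    for col in cohort.covariates.columns:
        df[col] = cohort.covariates[col].to_numpy()
    df.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> SexedCohort:
    df = pd.read_csv(path, sep="\t", dtype={"FID": str, "IID": str})
    required = {"FID", "IID", "sex", "phenotype"}
    if not required.issubset(df.columns):
        raise PlinkFormatError(
            f"phenotype table must have columns {sorted(required)}"
        )
    cov_cols = [c for c in df.columns if c not in required]
    return SexedCohort(
        ids=df["IID"].to_numpy(dtype=object),
        sex=df["sex"].to_numpy(),
        y=df["phenotype"].to_numpy(dtype=float),
        covariates=df[cov_cols].reset_index(drop=True),
    )


def write_id_list(ids, path: str | Path) -> None:
    """One individual ID per line (e.g. keep/remove lists from QC)."""
    with open(path, "w") as fh:
        for i in ids:
            fh.write(f"{i}\n")


def read_id_list(path: str | Path) -> np.ndarray:
    with open(path) as fh:
        return np.array([line.strip() for line in fh if line.strip()], dtype=object)


def write_truth(truth: GxsTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth(path: str | Path) -> GxsTruth:
    with open(path) as fh:
        return GxsTruth.from_dict(json.load(fh))
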