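"""Genotype standardization and the genomic relationship matrix (GRM).

The GRM K = Z Z' / M over M standardized SNPs induces the additive genetic
covariance among individuals in the mixed model.  Standardization statistics
(per-SNP mean and SD of reference-allele counts) always come from a
designated reference/training population and are frozen so the same
statistics can later standardize test genotypes for prediction.  Missing
calls are mean-imputed (contributing exactly 0 after standardization) and
the division is by M, not by per-pair non-missing counts, which keeps the
SNP-effect and GRM formulations of the model exactly equivalent.

The on-disk format is the GCTA binary triplet: ``.grm.bin`` (float32 lower
triangle, row-major), ``.grm.id`` (FID/IID text) and ``.grm.N.bin`` (float32
per-pair SNP counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simgen import GenotypeMatrix


class GrmFormatError(ValueError):
    pass


@dataclass
class Grm:
    ids: np.ndarray
    matrix: np.ndarray
    n_snps_used: int

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("GRM dimensions must match ID list")

    @property
    def n(self) -> int:
        return len(self.ids)

    def subset(self, keep: np.ndarray) -> "Grm":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return Grm(
            ids=self.ids[keep],
            matrix=self.matrix[np.ix_(keep, keep)],
            n_snps_used=self.n_snps_used,
        )


def standardize(
    geno: GenotypeMatrix,
    reference_ids: np.ndarray | None = None,
) -> tuple[np.ndarray, GenotypeMatrix]:
    """Column-standardize allele counts using reference-population statistics.

    Returns ``(Z, geno_out)`` where Z is the n x M' float matrix of
    (count - mu_j)/sigma_j values with missing entries set to 0, and
    ``geno_out`` is the input restricted to SNPs with sigma_j > 0, carrying
    the frozen ``ref_allele_mean``/``ref_allele_sd``.  The SD uses the
    population form (denominator n).
    """
    if reference_ids is None:
        ref_rows = np.arange(geno.n)
    else:
        ref_set = set(np.asarray(reference_ids, dtype=object).tolist())
        ref_rows = np.flatnonzero([i in ref_set for i in geno.ids])
        if len(ref_rows) != len(ref_set):
            raise ValueError("reference_ids must be a subset of genotype ids")
    counts = geno.counts.astype(float)
    miss = geno.missing_mask
    counts[miss] = np.nan

    ref = counts[ref_rows]
    with np.errstate(invalid="ignore"):
        mu = np.nanmean(ref, axis=0)
        sd = np.nanstd(ref, axis=0)  # ddof=0, population form
    all_missing = np.all(np.isnan(ref), axis=0)
    keep = (~all_missing) & (sd > 0)

    z = (counts[:, keep] - mu[keep]) / sd[keep]
    z[np.isnan(z)] = 0.0  # mean imputation

    out = geno.subset_snps(keep)
    out.ref_allele_mean = mu[keep]
    out.ref_allele_sd = sd[keep]
    return z, out


def compute_grm(z: np.ndarray) -> np.ndarray:
    """K = Z Z' / M over the M retained standardized SNPs."""
    z = np.asarray(z, dtype=float)
    if z.ndim != 2 or z.shape[1] == 0:
        raise ValueError("standardized matrix must be n x M with M >= 1")
    return (z @ z.T) / z.shape[1]


def grm_from_genotypes(
    geno: GenotypeMatrix, reference_ids: np.ndarray | None = None
) -> tuple[Grm, GenotypeMatrix]:
    """Standardize and cross-multiply in one step."""
    z, out = standardize(geno, reference_ids)
    return Grm(ids=out.ids, matrix=compute_grm(z), n_snps_used=out.m), out


# ---------------------------------------------------------------------------
# GCTA binary triplet


def write_grm(grm: Grm, prefix: str | Path) -> None:
    prefix = Path(prefix)
    n = grm.n
    tri = np.tril_indices(n)
    lower = grm.matrix[tri].astype(np.float32)
    lower.tofile(f"{prefix}.grm.bin")
    np.full(lower.shape, grm.n_snps_used, dtype=np.float32).tofile(
        f"{prefix}.grm.N.bin"
    )
    pd.DataFrame({"fid": grm.ids, "iid": grm.ids}).to_csv(
        f"{prefix}.grm.id", sep="\t", header=False, index=False
    )


def read_grm(prefix: str | Path) -> Grm:
    prefix = Path(prefix)
    ids = pd.read_csv(
        f"{prefix}.grm.id", sep=r"\s+", header=None, names=["fid", "iid"], dtype=str
    )["iid"].to_numpy(dtype=object)
    n = len(ids)
    lower = np.fromfile(f"{prefix}.grm.bin", dtype=np.float32)
    if lower.size != n * (n + 1) // 2:
        raise GrmFormatError(
            f"{prefix}.grm.bin holds {lower.size} values, expected "
            f"{n * (n + 1) // 2} for {n} ids"
        )
    mat = np.zeros((n, n))
    tri = np.tril_indices(n)
    mat[tri] = lower
    mat = mat + mat.T - np.diag(np.diag(mat))
    counts = np.fromfile(f"{prefix}.grm.N.bin", dtype=np.float32)
    m = int(round(float(counts[0]))) if counts.size else 0
    return Grm(ids=ids, matrix=mat, n_snps_used=m)
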