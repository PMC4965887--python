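"""Synthetic cohorts with a known sex-specific genetic architecture.

The generator mirrors the generative side of the sex-stratified bivariate
mixed model: a male/female cohort genotyped at M independent biallelic SNPs,
a causal subset whose per-SNP male/female effect pairs are drawn from a
zero-mean bivariate normal with cross-sex correlation ``rho``, sex-specific
total genetic variances, sex-specific residual variances, and fixed-effect
covariates.  Effects act on genotypes standardized by the *true* allele
frequency, so the realized genetic variance per sex targets ``sigma2_g_x``
exactly regardless of the MAF spectrum.

Randomness is governed by one integer seed with a documented stream order:
allele frequencies -> genotype draws -> missingness mask (stream 0), then
causal-SNP selection -> effect pairs -> covariates -> residuals (stream 1).
Two cohorts generated from the same truth are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = np.int8(-9)

MALE = 1
FEMALE = 2


class ConfigurationError(ValueError):
    """Raised when generator or filter parameters are invalid."""


@dataclass
class GxsTruth:
    """Generative parameters for one synthetic gene-by-sex cohort.

    Variances are on the trait scale; with the defaults the phenotypic
    variance is ~1 per sex, giving male/female heritabilities 0.3 and 0.4.
    """

    n_male: int = 1000
    n_female: int = 1000
    n_snps: int = 2000
    n_causal: int = 500
    maf_low: float = 0.05
    maf_high: float = 0.5
    sigma2_g_m: float = 0.3
    sigma2_g_f: float = 0.4
    rho: float = 0.7
    sigma2_e_m: float = 0.7
    sigma2_e_f: float = 0.6
    covariate_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"age": (0.1, 0.1)}
    )
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ConfigurationError(
                f"MAF bounds must satisfy 0 < low <= high <= 0.5, got "
                f"({self.maf_low}, {self.maf_high})"
            )
        for name in ("sigma2_g_m", "sigma2_g_f", "sigma2_e_m", "sigma2_e_f"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if abs(self.rho) > 1:
            raise ConfigurationError(f"|rho| must be <= 1, got {self.rho}")
        if self.n_causal > self.n_snps:
            raise ConfigurationError(
                f"n_causal ({self.n_causal}) exceeds n_snps ({self.n_snps})"
            )
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ConfigurationError("missing_rate must be in [0, 1]")

    @property
    def n(self) -> int:
        return self.n_male + self.n_female

    @property
    def h2_m(self) -> float:
        tot = self.sigma2_g_m + self.sigma2_e_m
        return self.sigma2_g_m / tot if tot > 0 else 0.0

    @property
    def h2_f(self) -> float:
        tot = self.sigma2_g_f + self.sigma2_e_f
        return self.sigma2_g_f / tot if tot > 0 else 0.0

    def to_dict(self) -> dict:
        return {
            "n_male": self.n_male,
            "n_female": self.n_female,
            "n_snps": self.n_snps,
            "n_causal": self.n_causal,
            "maf_low": self.maf_low,
            "maf_high": self.maf_high,
            "sigma2_g_m": self.sigma2_g_m,
            "sigma2_g_f": self.sigma2_g_f,
            "rho": self.rho,
            "sigma2_e_m": self.sigma2_e_m,
            "sigma2_e_f": self.sigma2_e_f,
            "covariate_effects": {
                k: list(v) for k, v in self.covariate_effects.items()
            },
            "missing_rate": self.missing_rate,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GxsTruth":
        d = dict(d)
        if "covariate_effects" in d:
            d["covariate_effects"] = {
                k: tuple(v) for k, v in d["covariate_effects"].items()
            }
        return cls(**d)


@dataclass
class GenotypeMatrix:
    """n x M reference-allele count matrix with SNP metadata.

    ``counts`` holds values in {0, 1, 2} with ``MISSING`` (-9) for missing
    calls.  ``ref_allele_mean``/``ref_allele_sd`` are per-SNP standardization
    statistics computed on a designated reference population (filled in by
    :func:`gxsreml.grm.standardize`); ``maf_true`` carries the generating
    allele frequency for simulated panels.
    """

    ids: np.ndarray
    snp_ids: np.ndarray
    counts: np.ndarray
    ref_allele_mean: np.ndarray | None = None
    ref_allele_sd: np.ndarray | None = None
    platform: np.ndarray | None = None
    maf_true: np.ndarray | None = None
    counts_complete: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.counts = np.asarray(self.counts, dtype=np.int8)
        if self.counts.shape != (len(self.ids), len(self.snp_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"({len(self.ids)}, {len(self.snp_ids)})"
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def m(self) -> int:
        return len(self.snp_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.counts == MISSING

    def subset_individuals(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Row subset by boolean mask or integer index array."""
        return GenotypeMatrix(
            ids=self.ids[keep],
            snp_ids=self.snp_ids,
            counts=self.counts[keep],
            ref_allele_mean=self.ref_allele_mean,
            ref_allele_sd=self.ref_allele_sd,
            platform=None if self.platform is None else self.platform[keep],
            maf_true=self.maf_true,
            counts_complete=(
                None if self.counts_complete is None else self.counts_complete[keep]
            ),
        )

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Column subset by boolean mask or integer index array."""

        def col(a):
            return None if a is None else a[keep]

        return GenotypeMatrix(
            ids=self.ids,
            snp_ids=self.snp_ids[keep],
            counts=self.counts[:, keep],
            ref_allele_mean=col(self.ref_allele_mean),
            ref_allele_sd=col(self.ref_allele_sd),
            platform=self.platform,
            maf_true=col(self.maf_true),
            counts_complete=(
                None
                if self.counts_complete is None
                else self.counts_complete[:, keep]
            ),
        )

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per SNP from non-missing calls."""
        obs = np.where(self.missing_mask, 0, self.counts).astype(float)
        n_obs = (~self.missing_mask).sum(axis=0)
        with np.errstate(invalid="ignore"):
            p = obs.sum(axis=0) / (2.0 * n_obs)
        p = np.where(n_obs == 0, np.nan, p)
        return np.minimum(p, 1.0 - p)


@dataclass
class SexedCohort:
    """Phenotype, sex labels and fixed-effect covariates for one cohort.

    ``sex`` uses the PLINK .fam convention: 1 = male, 2 = female.
    ``covariates`` is a DataFrame aligned row-wise with ``ids`` (the constant
    intercept column is added by the model code, not stored here).
    """

    ids: np.ndarray
    sex: np.ndarray
    y: np.ndarray
    covariates: pd.DataFrame
    truth: GxsTruth | None = None
    latent: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.sex = np.asarray(self.sex, dtype=np.int8)
        self.y = np.asarray(self.y, dtype=float)
        if not np.isin(self.sex, [MALE, FEMALE]).all():
            raise ValueError("sex labels must be 1 (male) or 2 (female)")
        if len(self.y) != len(self.ids) or len(self.sex) != len(self.ids):
            raise ValueError("ids, sex and y must have equal length")
        if len(self.covariates) != len(self.ids):
            raise ValueError("covariate row count must equal phenotype length")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def is_male(self) -> np.ndarray:
        return self.sex == MALE

    def subset(self, keep: np.ndarray) -> "SexedCohort":
        return SexedCohort(
            ids=self.ids[keep],
            sex=self.sex[keep],
            y=self.y[keep],
            covariates=self.covariates.iloc[np.arange(self.n)[keep]].reset_index(
                drop=True
            )
            if np.asarray(keep).dtype == bool
            else self.covariates.iloc[keep].reset_index(drop=True),
            truth=self.truth,
            latent=None if self.latent is None else self.latent[keep],
        )

    def with_phenotype(self, y: np.ndarray, latent: np.ndarray | None = None):
        return replace(self, y=np.asarray(y, dtype=float), latent=latent)


# ---------------------------------------------------------------------------
# generators


def _rng(truth: GxsTruth, stream: int) -> np.random.Generator:
    return np.random.default_rng([truth.seed, stream])


def simulate_genotypes(truth: GxsTruth, platforms: bool = False) -> GenotypeMatrix:
    """Draw a Hardy–Weinberg genotype panel with a uniform MAF spectrum.

    Per SNP j an allele frequency p_j ~ U(maf_low, maf_high); reference-allele
    counts are Binomial(2, p_j) per individual (no linkage disequilibrium).
    Entries are then masked missing independently with ``missing_rate``.  The
    complete (pre-masking) counts are retained for exact-truth phenotype
    simulation.
    """
    rng = _rng(truth, 0)
    n, m = truth.n, truth.n_snps
    p = rng.uniform(truth.maf_low, truth.maf_high, size=m)
    counts = rng.binomial(2, p[None, :], size=(n, m)).astype(np.int8)
    complete = counts.copy()
    if truth.missing_rate > 0:
        mask = rng.random(size=(n, m)) < truth.missing_rate
        counts = np.where(mask, MISSING, counts).astype(np.int8)
    ids = np.array([f"S{i:06d}" for i in range(n)], dtype=object)
    snp_ids = np.array([f"snp{j:06d}" for j in range(m)], dtype=object)
    platform = None
    if platforms:
        # alternate labels; deterministic, balanced
        platform = np.array(
            ["A" if i % 2 == 0 else "B" for i in range(n)], dtype=object
        )
    return GenotypeMatrix(
        ids=ids,
        snp_ids=snp_ids,
        counts=counts,
        platform=platform,
        maf_true=p,
        counts_complete=complete,
    )


def causal_effects(truth: GxsTruth, rng: np.random.Generator) -> np.ndarray:
    """Draw n_causal (male, female) effect pairs; returns (n_causal, 2).

    Pairs are zero-mean bivariate normal with variances sigma2_g_x/n_causal
    and correlation rho, so that the sum over causal SNPs of the per-SNP
    variances equals the total genetic variance per sex.
    """
    nc = truth.n_causal
    sm = np.sqrt(truth.sigma2_g_m / nc)
    sf = np.sqrt(truth.sigma2_g_f / nc)
    # explicit Cholesky-style construction, exact at |rho| = 1
    u = rng.standard_normal(nc)
    v = rng.standard_normal(nc)
    a_m = sm * u
    a_f = sf * (truth.rho * u + np.sqrt(max(0.0, 1.0 - truth.rho**2)) * v)
    return np.column_stack([a_m, a_f])


def simulate_phenotypes(geno: GenotypeMatrix, truth: GxsTruth) -> SexedCohort:
    """Generate sex-labelled phenotypes on top of a genotype panel.

    y_i = covariate effects + g_i + e_i where g_i is the dot product of the
    individual's causal genotypes (standardized by the true allele frequency)
    with the sex-matched effect vector, and e_i ~ N(0, sigma2_e_sex).  The
    first ``n_male`` individuals are male (fixed assignment, reproducible).
    """
    if geno.m < truth.n_causal:
        raise ConfigurationError(
            f"genotype panel has {geno.m} SNPs < n_causal={truth.n_causal}"
        )
    if geno.n != truth.n:
        raise ConfigurationError(
            f"genotype panel has {geno.n} individuals, truth expects {truth.n}"
        )
    rng = _rng(truth, 1)
    causal_idx = np.sort(rng.choice(geno.m, size=truth.n_causal, replace=False))
    effects = causal_effects(truth, rng)

    counts = geno.counts_complete if geno.counts_complete is not None else geno.counts
    counts = np.where(counts == MISSING, 0, counts).astype(float)
    if geno.maf_true is not None:
        p = geno.maf_true[causal_idx]
    else:  # fall back to sample frequency
        p = counts[:, causal_idx].mean(axis=0) / 2.0
    mu = 2.0 * p
    sd = np.sqrt(2.0 * p * (1.0 - p))
    z = (counts[:, causal_idx] - mu) / sd

    sex = np.full(geno.n, FEMALE, dtype=np.int8)
    sex[: truth.n_male] = MALE
    male = sex == MALE

    g = np.where(male, z @ effects[:, 0], z @ effects[:, 1])

    cov_cols = {}
    fixed = np.zeros(geno.n)
    for name, (beta_m, beta_f) in truth.covariate_effects.items():
        x = rng.standard_normal(geno.n)
        cov_cols[name] = x
        fixed += np.where(male, beta_m * x, beta_f * x)
    covariates = pd.DataFrame(cov_cols, index=range(geno.n))

    e_sd = np.where(male, np.sqrt(truth.sigma2_e_m), np.sqrt(truth.sigma2_e_f))
    e = rng.standard_normal(geno.n) * e_sd
    y = fixed + g + e

    cohort = SexedCohort(
        ids=geno.ids.copy(),
        sex=sex,
        y=y,
        covariates=covariates,
        truth=truth,
    )
    # stash realized genetic values for truth checks
    cohort.genetic_values = g  # type: ignore[attr-defined]
    return cohort


def simulate_categorical(
    cohort: SexedCohort,
    cuts_male: Sequence[float],
    cuts_female: Sequence[float],
) -> SexedCohort:
    """Threshold the latent phenotype into ordinal categories per sex.

    Category k means the latent value lies in (cut_{k-1}, cut_k]; with c cuts
    the categories are 0..c.  The latent values are retained on the returned
    cohort for truth checks.
    """
    for cuts, label in ((cuts_male, "male"), (cuts_female, "female")):
        arr = np.asarray(cuts, dtype=float)
        if arr.size == 0 or np.any(np.diff(arr) <= 0):
            raise ConfigurationError(
                f"{label} thresholds must be non-empty and strictly increasing"
            )
    latent = cohort.y.copy()
    cats = np.empty(cohort.n, dtype=float)
    male = cohort.is_male
    cats[male] = np.searchsorted(np.asarray(cuts_male, float), latent[male])
    cats[~male] = np.searchsorted(np.asarray(cuts_female, float), latent[~male])
    return cohort.with_phenotype(cats, latent=latent)


def split_train_test(
    cohort: SexedCohort,
    geno: GenotypeMatrix,
    test_fraction: float,
    seed: int,
) -> tuple[tuple[SexedCohort, GenotypeMatrix], tuple[SexedCohort, GenotypeMatrix]]:
    """Random disjoint train/test partition of a cohort and its genotypes.

    A simple (non-stratified) random split; errors out if either side ends up
    with fewer than two individuals of either sex.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ConfigurationError("test_fraction must be in (0, 1)")
    if not np.array_equal(cohort.ids, geno.ids):
        raise ValueError("cohort and genotype IDs must match")
    rng = np.random.default_rng(seed)
    n = cohort.n
    perm = rng.permutation(n)
    n_test = int(round(test_fraction * n))
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    for idx, label in ((train_idx, "train"), (test_idx, "test")):
        s = cohort.sex[idx]
        if (s == MALE).sum() < 2 or (s == FEMALE).sum() < 2:
            raise ValueError(
                f"{label} split has fewer than 2 individuals of one sex"
            )
    train = (cohort.subset(train_idx), geno.subset_individuals(train_idx))
    test = (cohort.subset(test_idx), geno.subset_individuals(test_idx))
    return train, test
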