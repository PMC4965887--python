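"""Genotype and phenotype quality-control filters.

Genotype-side filters (missingness, platform bias, Hardy–Weinberg, MAF
bands, relatedness pruning, ancestry window) and phenotype-side procedures
(per-sex outlier removal, ratio phenotypes, unit-SD rescaling, composite
first-PC scores, count caps, rank-based inverse-normal transform,
distribution-matched subsampling).  Every filter returns a QcReport whose
counts reconcile exactly, and every filter is idempotent.

Default thresholds: SNP missingness 2%, platform-bias Fisher P < 1e-100,
individual missingness 5%, Hardy–Weinberg P < 1e-50, relatedness 0.0625,
phenotype outliers at ±3 SD per sex, composite-score pre-exclusion at 5 SD,
offspring cap 15, ancestry window ±3 SD on 20 principal components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grm import Grm
from .simgen import ConfigurationError, GenotypeMatrix, SexedCohort


@dataclass
class QcReport:
    """Audit record for one QC stage: input − removed = output, always."""

    stage: str
    n_input: int
    n_removed: int
    threshold: object = None
    reasons: dict = field(default_factory=dict)

    @property
    def n_output(self) -> int:
        return self.n_input - self.n_removed

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "n_input": self.n_input,
            "n_removed": self.n_removed,
            "n_output": self.n_output,
            "threshold": self.threshold,
            "reasons": self.reasons,
        }


# ---------------------------------------------------------------------------
# genotype-side filters


def filter_snp_missingness(
    geno: GenotypeMatrix, max_rate: float = 0.02
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop SNPs whose missing-call fraction exceeds ``max_rate``."""
    if not 0.0 <= max_rate <= 1.0:
        raise ConfigurationError("max_rate must be in [0, 1]")
    rate = geno.missing_mask.mean(axis=0)
    keep = rate <= max_rate
    if not keep.any():
        raise ValueError("SNP missingness filter removed every SNP")
    report = QcReport(
        stage="snp_missingness",
        n_input=geno.m,
        n_removed=int((~keep).sum()),
        threshold=max_rate,
    )
    return geno.subset_snps(keep), report


def filter_individual_missingness(
    geno: GenotypeMatrix, max_rate: float = 0.05
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop individuals whose missing-call fraction exceeds ``max_rate``."""
    if not 0.0 <= max_rate <= 1.0:
        raise ConfigurationError("max_rate must be in [0, 1]")
    rate = geno.missing_mask.mean(axis=1)
    keep = rate <= max_rate
    if not keep.any():
        raise ValueError("individual missingness filter removed everyone")
    report = QcReport(
        stage="individual_missingness",
        n_input=geno.n,
        n_removed=int((~keep).sum()),
        threshold=max_rate,
    )
    return geno.subset_individuals(keep), report


def platform_bias_filter(
    geno: GenotypeMatrix, p_threshold: float = 1e-100
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop SNPs whose missingness differs between genotyping platforms.

    Per SNP, a two-sided Fisher's exact test on the 2x2 table of
    (missing, observed) x (platform A, platform B).
    """
    if geno.platform is None:
        raise ValueError("platform labels are required for the bias filter")
    labels = np.unique(geno.platform)
    if len(labels) != 2:
        raise ValueError(f"exactly two platforms required, got {len(labels)}")
    on_a = geno.platform == labels[0]
    miss = geno.missing_mask
    miss_a = miss[on_a].sum(axis=0)
    miss_b = miss[~on_a].sum(axis=0)
    n_a, n_b = int(on_a.sum()), int((~on_a).sum())
    pvals = np.ones(geno.m)
    # Fisher only needed when any missingness is present
    for j in np.flatnonzero((miss_a + miss_b) > 0):
        table = [
            [int(miss_a[j]), n_a - int(miss_a[j])],
            [int(miss_b[j]), n_b - int(miss_b[j])],
        ]
        pvals[j] = stats.fisher_exact(table, alternative="two-sided")[1]
    keep = pvals >= p_threshold
    report = QcReport(
        stage="platform_bias",
        n_input=geno.m,
        n_removed=int((~keep).sum()),
        threshold=p_threshold,
    )
    return geno.subset_snps(keep), report


def hwe_statistics(
    geno: GenotypeMatrix, reference_ids: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP 1-df chi-square statistic and P for Hardy–Weinberg fit.

    Computed from observed genotype-class counts vs expectations under the
    sample allele frequency in the reference subset.  Monomorphic SNPs get
    statistic 0 and P = 1.
    """
    if reference_ids is not None:
        ref_set = set(np.asarray(reference_ids, dtype=object).tolist())
        rows = np.flatnonzero([i in ref_set for i in geno.ids])
    else:
        rows = np.arange(geno.n)
    counts = geno.counts[rows]
    obs = ~geno.missing_mask[rows]
    n_obs = obs.sum(axis=0).astype(float)
    n_aa = ((counts == 2) & obs).sum(axis=0).astype(float)
    n_het = ((counts == 1) & obs).sum(axis=0).astype(float)
    n_bb = ((counts == 0) & obs).sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (2 * n_aa + n_het) / (2 * n_obs)
        e_aa = n_obs * p**2
        e_het = n_obs * 2 * p * (1 - p)
        e_bb = n_obs * (1 - p) ** 2
        chi2 = (
            (n_aa - e_aa) ** 2 / e_aa
            + (n_het - e_het) ** 2 / e_het
            + (n_bb - e_bb) ** 2 / e_bb
        )
    mono = (p <= 0) | (p >= 1) | (n_obs == 0)
    chi2 = np.where(mono, 0.0, chi2)
    chi2 = np.nan_to_num(chi2, nan=0.0)
    pvals = stats.chi2.sf(chi2, df=1)
    pvals = np.where(mono, 1.0, pvals)
    return chi2, pvals


def hwe_filter(
    geno: GenotypeMatrix,
    p_threshold: float = 1e-50,
    reference_ids: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop SNPs departing from Hardy–Weinberg equilibrium in the reference set."""
    if reference_ids is not None and len(reference_ids) == 0:
        raise ValueError("reference_ids must be nonempty")
    chi2, pvals = hwe_statistics(geno, reference_ids)
    keep = pvals >= p_threshold
    mono = (chi2 == 0) & (pvals == 1.0)
    report = QcReport(
        stage="hwe",
        n_input=geno.m,
        n_removed=int((~keep).sum()),
        threshold=p_threshold,
        reasons={"monomorphic_flagged": int(mono.sum())},
    )
    return geno.subset_snps(keep), report


def maf_band_filter(
    geno: GenotypeMatrix, low: float = 0.05, high: float = 0.5
) -> tuple[GenotypeMatrix, QcReport]:
    """Retain SNPs with minor-allele frequency in (low, high]."""
    if not (0.0 <= low < high <= 0.5):
        raise ConfigurationError("need 0 <= low < high <= 0.5")
    maf = geno.maf()
    keep = (maf > low) & (maf <= high)
    report = QcReport(
        stage="maf_band",
        n_input=geno.m,
        n_removed=int((~keep).sum()),
        threshold=(low, high),
    )
    return geno.subset_snps(keep), report


def _related_pairs(grm: Grm, threshold: float) -> np.ndarray:
    mat = grm.matrix
    iu = np.triu_indices(grm.n, k=1)
    above = mat[iu] > threshold
    return np.column_stack([iu[0][above], iu[1][above]])


def relatedness_prune(
    grm: Grm, threshold: float = 0.0625
) -> tuple[np.ndarray, np.ndarray, QcReport]:
    """Greedy pruning so no kept pair has relatedness above ``threshold``.

    While any pair exceeds the threshold, remove the individual in the most
    such pairs (ties broken by lexicographically smallest ID).  Returns
    (kept ids, removed ids, report).
    """
    pairs = _related_pairs(grm, threshold)
    removed: list[int] = []
    if len(pairs):
        degree = np.zeros(grm.n, dtype=int)
        np.add.at(degree, pairs[:, 0], 1)
        np.add.at(degree, pairs[:, 1], 1)
        alive_pairs = pairs
        while len(alive_pairs):
            maxdeg = degree.max()
            cand = np.flatnonzero(degree == maxdeg)
            # lexicographically smallest ID among max-degree candidates
            victim = cand[np.argmin(grm.ids[cand].astype(str))]
            removed.append(int(victim))
            involved = (alive_pairs[:, 0] == victim) | (alive_pairs[:, 1] == victim)
            for a, b in alive_pairs[involved]:
                degree[a] -= 1
                degree[b] -= 1
            alive_pairs = alive_pairs[~involved]
    removed_arr = np.array(sorted(removed), dtype=int)
    keep_mask = np.ones(grm.n, dtype=bool)
    keep_mask[removed_arr] = False
    report = QcReport(
        stage="relatedness_prune",
        n_input=grm.n,
        n_removed=len(removed),
        threshold=threshold,
    )
    return grm.ids[keep_mask], grm.ids[~keep_mask], report


def extract_related_cohort(grm: Grm, threshold: float = 0.0625) -> np.ndarray:
    """IDs of individuals with at least one partner above ``threshold``."""
    pairs = _related_pairs(grm, threshold)
    if not len(pairs):
        return np.array([], dtype=object)
    idx = np.unique(pairs)
    return grm.ids[idx]


def _fix_sign(scores: np.ndarray, loadings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Make each component's largest-|loading| entry positive (deterministic sign)."""
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] = -loadings[:, k]
            scores[:, k] = -scores[:, k]
    return scores, loadings


def compute_pcs(geno: GenotypeMatrix, k: int = 20) -> np.ndarray:
    """Scores of the k leading principal components of standardized genotypes.

    Missing calls are mean-imputed before standardization; component signs
    are fixed by making each component's largest-magnitude SNP loading
    positive.
    """
    from .grm import standardize

    if k > min(geno.n, geno.m):
        raise ValueError(f"k={k} exceeds min(n, M)={min(geno.n, geno.m)}")
    z, _ = standardize(geno)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = u[:, :k] * s[:k]
    scores, _ = _fix_sign(scores, vt[:k].T.copy())
    return scores


def ancestry_window_filter(
    pcs: np.ndarray, ids: np.ndarray, sd_multiplier: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Keep individuals within ±sd_multiplier SD of the mean on every component.

    Returns (kept ids, excluded ids); the excluded set is the natural test
    cohort for out-of-window genomic prediction.
    """
    pcs = np.asarray(pcs, dtype=float)
    mean = pcs.mean(axis=0)
    sd = pcs.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    inside = (np.abs(pcs - mean) <= sd_multiplier * sd).all(axis=1)
    ids = np.asarray(ids, dtype=object)
    return ids[inside], ids[~inside]


# ---------------------------------------------------------------------------
# phenotype-side procedures


def per_sex_outlier_removal(
    cohort: SexedCohort, sd: float = 3.0
) -> tuple[SexedCohort, QcReport]:
    """Remove individuals beyond ±sd SDs from their own sex's phenotype mean.

    Means and SDs are computed once on the pre-filter cohort (no iteration).
    """
    keep = np.ones(cohort.n, dtype=bool)
    for male in (True, False):
        rows = cohort.is_male == male
        y = cohort.y[rows]
        if len(y) == 0:
            continue
        mu, sigma = y.mean(), y.std(ddof=1) if len(y) > 1 else 0.0
        if sigma > 0:
            keep[rows] = np.abs(y - mu) <= sd * sigma
    report = QcReport(
        stage="per_sex_outliers",
        n_input=cohort.n,
        n_removed=int((~keep).sum()),
        threshold=sd,
    )
    return cohort.subset(keep), report


def derive_ratio(cohort_num: SexedCohort, cohort_den: SexedCohort) -> SexedCohort:
    """Elementwise ratio phenotype (e.g. waist/hip, FEV1/FVC)."""
    if not np.array_equal(cohort_num.ids, cohort_den.ids):
        raise ValueError("numerator and denominator cohorts must share IDs")
    if np.any(cohort_den.y == 0):
        raise ValueError("denominator phenotype contains zeros")
    return cohort_num.with_phenotype(cohort_num.y / cohort_den.y)


def rescale_unit_sd(cohort: SexedCohort) -> SexedCohort:
    """Divide the phenotype by its whole-cohort SD (no centering)."""
    sd = cohort.y.std(ddof=1)
    if sd == 0:
        raise ValueError("phenotype SD is zero; cannot rescale")
    return cohort.with_phenotype(cohort.y / sd)


def composite_pc_score(
    measures: pd.DataFrame, exclusion_sd: float = 5.0
) -> tuple[pd.Series, QcReport]:
    """First-principal-component score of several standardized measures.

    Individuals more than ``exclusion_sd`` SDs from the population mean on
    any measure are excluded before the PCA.  Returns scores indexed by the
    surviving rows of ``measures``.
    """
    if measures.shape[1] < 2:
        raise ValueError("at least two measures are required")
    x = measures.to_numpy(dtype=float)
    mu, sd = x.mean(axis=0), x.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    keep = (np.abs(x - mu) <= exclusion_sd * sd).all(axis=1)
    xs = (x[keep] - x[keep].mean(axis=0)) / x[keep].std(axis=0, ddof=1)
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    scores = u[:, :1] * s[:1]
    scores, _ = _fix_sign(scores, vt[:1].T.copy())
    report = QcReport(
        stage="composite_pc_score",
        n_input=len(measures),
        n_removed=int((~keep).sum()),
        threshold=exclusion_sd,
    )
    return pd.Series(scores[:, 0], index=measures.index[keep]), report


def cap_count_phenotype(
    cohort: SexedCohort, max_value: float = 15
) -> tuple[SexedCohort, QcReport]:
    """Exclude individuals whose count phenotype exceeds ``max_value``."""
    keep = cohort.y <= max_value
    report = QcReport(
        stage="count_cap",
        n_input=cohort.n,
        n_removed=int((~keep).sum()),
        threshold=max_value,
    )
    return cohort.subset(keep), report


def rank_inverse_normal(cohort: SexedCohort, within_sex: bool = False) -> SexedCohort:
    """Rank-based inverse-normal transform: Phi^{-1}((rank - 0.5)/n).

    Ties receive their average rank; with ``within_sex`` the transform is
    applied separately inside each sex.
    """
    y = cohort.y.copy()

    def transform(v: np.ndarray) -> np.ndarray:
        ranks = stats.rankdata(v, method="average")
        return stats.norm.ppf((ranks - 0.5) / len(v))

    if within_sex:
        for male in (True, False):
            rows = cohort.is_male == male
            if rows.sum():
                y[rows] = transform(cohort.y[rows])
    else:
        y = transform(y)
    return cohort.with_phenotype(y)


def match_distributions(
    cohort: SexedCohort, seed: int = 0
) -> tuple[np.ndarray, QcReport]:
    """Subsample so both sexes share an identical categorical distribution.

    Per phenotype stratum, all individuals of the minority sex are kept and
    an equal-size uniform random sample (without replacement) is drawn from
    the majority sex.  Strata present in only one sex are dropped entirely.
    Returns (kept ids, report).
    """
    values = np.unique(cohort.y)
    if len(values) > max(50, int(np.sqrt(cohort.n)) + 1):
        raise ValueError(
            "phenotype does not look categorical (too many distinct values)"
        )
    rng = np.random.default_rng(seed)
    keep_idx: list[np.ndarray] = []
    dropped_strata: list[float] = []
    for v in values:
        stratum = cohort.y == v
        males = np.flatnonzero(stratum & cohort.is_male)
        females = np.flatnonzero(stratum & ~cohort.is_male)
        if len(males) == 0 or len(females) == 0:
            dropped_strata.append(float(v))
            continue
        k = min(len(males), len(females))
        for grp in (males, females):
            if len(grp) == k:
                keep_idx.append(grp)
            else:
                keep_idx.append(rng.choice(grp, size=k, replace=False))
    idx = np.sort(np.concatenate(keep_idx)) if keep_idx else np.array([], dtype=int)
    report = QcReport(
        stage="match_distributions",
        n_input=cohort.n,
        n_removed=cohort.n - len(idx),
        threshold=None,
        reasons={"dropped_strata": dropped_strata, "seed": seed},
    )
    return cohort.ids[idx], report
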