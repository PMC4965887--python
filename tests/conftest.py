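import numpy as np
import pandas as pd
import pytest

from gxsreml.grm import Grm, compute_grm, standardize
from gxsreml.simgen import GxsTruth, SexedCohort, simulate_genotypes, simulate_phenotypes


def geno_from_counts(counts, platform=None):
    """GenotypeMatrix from a raw count array, with generated IDs."""
    from gxsreml.simgen import GenotypeMatrix

    counts = np.asarray(counts, dtype=np.int8)
    n, m = counts.shape
    return GenotypeMatrix(
        ids=np.array([f"i{i}" for i in range(n)], dtype=object),
        snp_ids=np.array([f"s{j}" for j in range(m)], dtype=object),
        counts=counts,
        platform=platform,
    )


def make_cohort(truth: GxsTruth):
    """Simulate genotypes + phenotypes and build the GRM in one go."""
    geno = simulate_genotypes(truth)
    cohort = simulate_phenotypes(geno, truth)
    z, geno_std = standardize(geno)
    grm = Grm(ids=geno_std.ids, matrix=compute_grm(z), n_snps_used=geno_std.m)
    return geno, cohort, grm, z, geno_std


@pytest.fixture(scope="session")
def small_truth():
    return GxsTruth(
        n_male=200,
        n_female=200,
        n_snps=400,
        n_causal=120,
        rho=0.7,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_truth):
    """(geno, cohort, grm, z, geno_std) at a size where fits take ~a second."""
    return make_cohort(small_truth)


@pytest.fixture()
def tiny_problem():
    """A 12-individual toy: K, sexed cohort with one covariate."""
    rng = np.random.default_rng(42)
    n, nm = 12, 5
    z = rng.normal(size=(n, 17))
    k = z @ z.T / 17
    ids = np.array([f"i{j:02d}" for j in range(n)], dtype=object)
    sex = np.array([1] * nm + [2] * (n - nm), dtype=np.int8)
    cohort = SexedCohort(
        ids=ids,
        sex=sex,
        y=rng.normal(size=n),
        covariates=pd.DataFrame({"age": rng.normal(size=n)}),
    )
    grm = Grm(ids=ids, matrix=k, n_snps_used=17)
    return grm, cohort


def dense_restricted_loglik(k, sex, y, x, sg2_m, sg2_f, rho, se2_m, se2_f):
    """Independent dense REML likelihood from the explicit projection formula.

    Builds V entry by entry from the covariance definition and uses plain
    inverses/slogdet — no Cholesky tricks, no code shared with the package.
    """
    n = len(y)
    c = {
        (1, 1): sg2_m,
        (2, 2): sg2_f,
        (1, 2): rho * np.sqrt(sg2_m * sg2_f),
        (2, 1): rho * np.sqrt(sg2_m * sg2_f),
    }
    v = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            v[i, j] = c[(sex[i], sex[j])] * k[i, j]
        v[i, i] += se2_m if sex[i] == 1 else se2_f
    vi = np.linalg.inv(v)
    xtvix = x.T @ vi @ x
    p = vi - vi @ x @ np.linalg.inv(xtvix) @ x.T @ vi
    return -0.5 * (
        np.linalg.slogdet(v)[1] + np.linalg.slogdet(xtvix)[1] + y @ p @ y
    )
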