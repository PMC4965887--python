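import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gxsreml.grm import Grm
from gxsreml.qc import (
    ancestry_window_filter,
    cap_count_phenotype,
    composite_pc_score,
    compute_pcs,
    derive_ratio,
    extract_related_cohort,
    filter_individual_missingness,
    filter_snp_missingness,
    hwe_filter,
    hwe_statistics,
    maf_band_filter,
    match_distributions,
    per_sex_outlier_removal,
    platform_bias_filter,
    rank_inverse_normal,
    relatedness_prune,
    rescale_unit_sd,
)
from gxsreml.simgen import MISSING, GxsTruth, SexedCohort, simulate_genotypes

from conftest import geno_from_counts


def make_sexed(y, sex=None, ids=None, cov=None):
    y = np.asarray(y, dtype=float)
    n = len(y)
    if sex is None:
        sex = np.array([1] * (n // 2) + [2] * (n - n // 2))
    if ids is None:
        ids = np.array([f"i{j:03d}" for j in range(n)], dtype=object)
    return SexedCohort(
        ids=np.asarray(ids, dtype=object),
        sex=np.asarray(sex),
        y=y,
        covariates=cov if cov is not None else pd.DataFrame(index=range(n)),
    )


def geno_with_missing(col_missing_counts, n=100):
    """m SNPs over n individuals; SNP j has col_missing_counts[j] missing calls."""
    m = len(col_missing_counts)
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    for j, k in enumerate(col_missing_counts):
        counts[:k, j] = MISSING
    return geno_from_counts(counts)


class TestMissingness:
    def test_snp_counts_filtered_exactly(self):
        geno = geno_with_missing([0, 1, 2, 3, 4])
        out, rep = filter_snp_missingness(geno, max_rate=0.02)
        assert out.m == 3  # 0,1,2 of 100 kept; 3,4 removed
        assert rep.n_input - rep.n_removed == rep.n_output == 3

    def test_individual_counts_filtered_exactly(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 3, size=(3, 100)).astype(np.int8)
        counts[1, :5] = MISSING
        counts[2, :6] = MISSING
        out, rep = filter_individual_missingness(geno_from_counts(counts), 0.05)
        assert out.n == 2 and rep.n_removed == 1

    def test_idempotent(self):
        geno = geno_with_missing([0, 1, 2, 3, 4])
        once, _ = filter_snp_missingness(geno, 0.02)
        twice, rep = filter_snp_missingness(once, 0.02)
        assert rep.n_removed == 0
        assert np.array_equal(once.counts, twice.counts)


class TestPlatformBias:
    def _geno(self, miss_a, miss_b, n_a=50, n_b=50):
        counts = np.ones((n_a + n_b, 1), dtype=np.int8)
        counts[:miss_a, 0] = MISSING
        counts[n_a : n_a + miss_b, 0] = MISSING
        platform = np.array(["A"] * n_a + ["B"] * n_b, dtype=object)
        return geno_from_counts(counts, platform=platform)

    def test_balanced_missingness_kept(self):
        out, rep = platform_bias_filter(self._geno(5, 5), 1e-100)
        assert out.m == 1 and rep.n_removed == 0

    def test_total_separation_removed(self):
        # all 50 missing calls on platform A only: exact hypergeometric tail
        geno = self._geno(50, 0)
        p_exact = stats.hypergeom.pmf(50, 100, 50, 50)
        out, rep = platform_bias_filter(geno, p_threshold=10 * p_exact)
        assert rep.n_removed == 1

    def test_mild_imbalance_kept_at_extreme_threshold(self):
        out, rep = platform_bias_filter(self._geno(1, 2), 1e-100)
        assert rep.n_removed == 0

    def test_requires_two_platforms(self):
        geno = self._geno(1, 1)
        geno.platform = np.array(["A"] * 100, dtype=object)
        with pytest.raises(ValueError):
            platform_bias_filter(geno)


class TestHwe:
    def _geno_from_genotype_counts(self, n_aa, n_het, n_bb):
        counts = np.array([2] * n_aa + [1] * n_het + [0] * n_bb, dtype=np.int8)
        return geno_from_counts(counts[:, None])

    def test_exact_proportions_pass(self):
        geno = self._geno_from_genotype_counts(25, 50, 25)
        chi2, p = hwe_statistics(geno)
        assert chi2[0] == pytest.approx(0.0, abs=1e-12)
        assert p[0] == pytest.approx(1.0)

    def test_no_heterozygotes_removed(self):
        geno = self._geno_from_genotype_counts(50, 0, 50)
        chi2, p = hwe_statistics(geno)
        assert chi2[0] == pytest.approx(100.0)  # equals n
        out, rep = hwe_filter(geno, p_threshold=1e-6)
        assert rep.n_removed == 1

    def test_statistic_matches_independent_formula(self):
        n_aa, n_het, n_bb = 30, 40, 30
        geno = self._geno_from_genotype_counts(n_aa, n_het, n_bb)
        chi2, _ = hwe_statistics(geno)
        n = n_aa + n_het + n_bb
        p = (2 * n_aa + n_het) / (2 * n)
        exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
        obs = np.array([n_aa, n_het, n_bb])
        assert chi2[0] == pytest.approx(((obs - exp) ** 2 / exp).sum(), rel=1e-12)

    def test_monomorphic_kept_with_p_one(self):
        geno = geno_from_counts(np.zeros((10, 1), dtype=np.int8))
        out, rep = hwe_filter(geno, p_threshold=0.99)
        assert rep.n_removed == 0 and rep.reasons["monomorphic_flagged"] == 1


class TestMafBand:
    def test_boundary_cases_and_hand_count(self):
        # MAFs: 0.003, 0.02, 0.3, 0.5, 0.04
        def col(p, n=1000):
            k = int(round(2 * n * p))
            c = np.zeros(n, dtype=np.int8)
            c[: k // 2] = 2
            if k % 2:
                c[k // 2] = 1
            return c

        counts = np.column_stack([col(p) for p in (0.003, 0.02, 0.3, 0.5, 0.04)])
        geno = geno_from_counts(counts)
        common, _ = maf_band_filter(geno, 0.05, 0.5)
        assert set(common.snp_ids) == {"s2", "s3"}  # 0.5 kept, 0.04 removed
        combined, _ = maf_band_filter(geno, 0.0037, 0.5)
        assert set(combined.snp_ids) == {"s1", "s2", "s3", "s4"}


def grm_from_pairs(n, pairs, value=0.2):
    mat = np.eye(n)
    for a, b in pairs:
        mat[a, b] = mat[b, a] = value
    ids = np.array([f"i{j}" for j in range(n)], dtype=object)
    return Grm(ids=ids, matrix=mat, n_snps_used=10)


class TestRelatedness:
    def test_no_related_pairs_all_kept(self):
        kept, removed, _ = relatedness_prune(grm_from_pairs(5, []))
        assert len(kept) == 5 and len(removed) == 0

    def test_single_pair_one_removed(self):
        kept, removed, _ = relatedness_prune(grm_from_pairs(4, [(0, 1)]))
        assert len(removed) == 1 and removed[0] in {"i0", "i1"}

    def test_star_graph_removes_hub_only(self):
        g = grm_from_pairs(6, [(2, 3), (2, 4), (2, 5)])
        kept, removed, _ = relatedness_prune(g)
        assert list(removed) == ["i2"]
        assert len(kept) == 5

    def test_no_kept_pair_exceeds_threshold_and_near_minimal(self):
        rng = np.random.default_rng(7)
        n = 10
        pairs = [(a, b) for a in range(n) for b in range(a + 1, n) if rng.random() < 0.2]
        g = grm_from_pairs(n, pairs)
        kept, removed, _ = relatedness_prune(g)
        kept_idx = [int(i[1:]) for i in kept]
        for a in kept_idx:
            for b in kept_idx:
                if a < b:
                    assert g.matrix[a, b] <= 0.0625
        # brute-force minimum vertex cover on the toy graph
        best = n
        for mask in range(1 << n):
            cover = {v for v in range(n) if mask >> v & 1}
            if all(a in cover or b in cover for a, b in pairs):
                best = min(best, len(cover))
        assert len(removed) <= best + 2  # greedy may exceed the optimum slightly

    def test_extract_related_cohort(self):
        g = grm_from_pairs(6, [(0, 1), (3, 4)])
        assert set(extract_related_cohort(g)) == {"i0", "i1", "i3", "i4"}
        assert len(extract_related_cohort(grm_from_pairs(4, []))) == 0


class TestPca:
    def test_identical_individuals_identical_scores(self):
        counts = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, 0, 1, 0], [1, 2, 0, 2]])
        scores = compute_pcs(geno_from_counts(counts), k=2)
        np.testing.assert_allclose(scores[0], scores[1], atol=1e-10)

    def test_scores_match_dense_eigendecomposition(self):
        t = GxsTruth(n_male=25, n_female=25, n_snps=100, n_causal=10, seed=2)
        geno = simulate_genotypes(t)
        scores = compute_pcs(geno, k=5)
        from gxsreml.grm import standardize

        z, _ = standardize(geno)
        w, v = np.linalg.eigh(z @ z.T)
        idx = np.argsort(w)[::-1][:5]
        ref = v[:, idx] * np.sqrt(w[idx])
        for k in range(5):
            r = ref[:, k] if ref[:, k] @ scores[:, k] > 0 else -ref[:, k]
            np.testing.assert_allclose(scores[:, k], r, atol=1e-8)

    def test_k_too_large_rejected(self):
        geno = geno_from_counts(np.random.default_rng(0).integers(0, 3, (5, 8)))
        with pytest.raises(ValueError):
            compute_pcs(geno, k=6)

    def test_ancestry_window(self):
        pcs = np.zeros((6, 3))
        pcs[:, 0] = [0.0, 0.1, -0.1, 0.05, -0.05, 4.0]  # last one is an outlier
        ids = np.array([f"i{j}" for j in range(6)], dtype=object)
        kept, excluded = ancestry_window_filter(pcs, ids, sd_multiplier=2)
        assert list(excluded) == ["i5"]
        all_kept, none = ancestry_window_filter(np.zeros((4, 2)), ids[:4])
        assert len(all_kept) == 4 and len(none) == 0


class TestPhenotypeFilters:
    def test_outliers_match_hand_computation(self):
        y = np.array([1.0, 2.0, 3.0, 2.0, 50.0, 5.0, 6.0, 7.0, 6.0, 5.0])
        sex = np.array([1] * 5 + [2] * 5)
        cohort = make_sexed(y, sex)
        out, rep = per_sex_outlier_removal(cohort, sd=3)
        # male mean/SD over (1,2,3,2,50): mean 11.6, sd 21.5 -> all within 3 SD
        m_y = y[:5]
        keep_m = np.abs(m_y - m_y.mean()) <= 3 * m_y.std(ddof=1)
        assert rep.n_removed == int((~keep_m).sum())

    def test_extreme_value_removed(self):
        y = np.concatenate([np.random.default_rng(0).normal(size=49), [30.0]])
        cohort = make_sexed(y, sex=np.array([1] * 50))
        out, rep = per_sex_outlier_removal(cohort, sd=3)
        assert "i049" not in out.ids

    def test_constant_phenotype_none_removed(self):
        cohort = make_sexed(np.ones(10))
        out, rep = per_sex_outlier_removal(cohort)
        assert rep.n_removed == 0

    def test_ratio_matches_elementwise_division(self):
        rng = np.random.default_rng(3)
        num, den = rng.normal(2, 0.1, 20), rng.normal(4, 0.1, 20)
        c = derive_ratio(make_sexed(num), make_sexed(den))
        np.testing.assert_allclose(c.y, num / den)

    def test_rescale_unit_sd(self):
        rng = np.random.default_rng(4)
        y = rng.normal(5, 3, 100)
        c = rescale_unit_sd(make_sexed(y))
        assert c.y.std(ddof=1) == pytest.approx(1.0)
        np.testing.assert_allclose(c.y, y / y.std(ddof=1))
        with pytest.raises(ValueError):
            rescale_unit_sd(make_sexed(np.ones(5)))

    def test_composite_score_proportional_for_correlated_measures(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=40)
        df = pd.DataFrame({"a": base, "b": 2 * base + 1})
        scores, rep = composite_pc_score(df)
        r = np.corrcoef(scores, base)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_composite_score_excludes_extreme_then_matches_eigensolve(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(50, 3)), columns=["a", "b", "c"])
        df.iloc[0, 0] = 100.0  # > 5 SD
        scores, rep = composite_pc_score(df, exclusion_sd=5)
        assert rep.n_removed == 1 and 0 not in scores.index
        x = df.iloc[1:].to_numpy()
        xs = (x - x.mean(0)) / x.std(0, ddof=1)
        w, v = np.linalg.eigh(xs.T @ xs)
        lead = v[:, np.argmax(w)]
        ref = xs @ lead
        r = np.corrcoef(scores.to_numpy(), ref)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_count_cap_hand_count(self):
        cohort = make_sexed([0, 3, 15, 16, 20], sex=np.array([1, 1, 1, 2, 2]))
        out, rep = cap_count_phenotype(cohort, 15)
        assert out.n == 3 and rep.n_removed == 2  # 15 kept ("in excess of")


class TestRankInverseNormal:
    def test_monotone_in_input(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=51)
        c = rank_inverse_normal(make_sexed(y))
        order = np.argsort(y)
        assert np.all(np.diff(c.y[order]) >= 0)

    def test_size_two_closed_form(self):
        c = rank_inverse_normal(make_sexed([3.0, 1.0], sex=np.array([1, 2])))
        z = stats.norm.ppf(0.25)
        np.testing.assert_allclose(sorted(c.y), [z, -z], atol=1e-12)

    def test_large_sample_standardized(self):
        rng = np.random.default_rng(8)
        c = rank_inverse_normal(make_sexed(rng.exponential(size=1000)))
        assert abs(c.y.mean()) < 0.01
        assert c.y.std() == pytest.approx(1.0, abs=0.02)

    def test_within_sex_flag(self):
        rng = np.random.default_rng(9)
        y = np.concatenate([rng.normal(10, 1, 50), rng.normal(0, 1, 50)])
        c = rank_inverse_normal(make_sexed(y), within_sex=True)
        assert abs(c.y[:50].mean()) < 0.05 and abs(c.y[50:].mean()) < 0.05


class TestMatchDistributions:
    def _cohort(self, male_counts, female_counts):
        y, sex = [], []
        for v, k in male_counts.items():
            y += [v] * k
            sex += [1] * k
        for v, k in female_counts.items():
            y += [v] * k
            sex += [2] * k
        return make_sexed(np.array(y, float), np.array(sex))

    def test_min_per_stratum(self):
        cohort = self._cohort({0: 10, 1: 5}, {0: 6, 1: 8})
        ids, rep = match_distributions(cohort, seed=0)
        kept = cohort.subset(np.isin(cohort.ids, ids))
        for v, expect in ((0, 6), (1, 5)):
            assert (kept.y[kept.is_male] == v).sum() == expect
            assert (kept.y[~kept.is_male] == v).sum() == expect
        assert len(ids) == 22

    def test_already_equal_all_kept(self):
        cohort = self._cohort({0: 4, 1: 6}, {0: 4, 1: 6})
        ids, rep = match_distributions(cohort, seed=1)
        assert len(ids) == cohort.n and rep.n_removed == 0

    def test_single_sex_stratum_dropped(self):
        cohort = self._cohort({0: 3, 2: 4}, {0: 3, 1: 5})
        ids, rep = match_distributions(cohort, seed=2)
        kept = cohort.subset(np.isin(cohort.ids, ids))
        assert set(np.unique(kept.y)) == {0.0}
        assert sorted(rep.reasons["dropped_strata"]) == [1.0, 2.0]

    def test_chi_square_of_sex_by_stratum_is_zero(self):
        rng = np.random.default_rng(10)
        y = rng.integers(0, 4, 200).astype(float)
        sex = np.where(rng.random(200) < 0.6, 1, 2)
        cohort = make_sexed(y, sex)
        ids, _ = match_distributions(cohort, seed=3)
        kept = cohort.subset(np.isin(cohort.ids, ids))
        table = pd.crosstab(kept.sex, kept.y)
        chi2 = stats.chi2_contingency(table)[0] if table.size else 0.0
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_given_seed(self):
        cohort = self._cohort({0: 10, 1: 7}, {0: 5, 1: 9})
        a, _ = match_distributions(cohort, seed=5)
        b, _ = match_distributions(cohort, seed=5)
        assert np.array_equal(a, b)
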