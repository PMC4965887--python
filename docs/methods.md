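# Methods

## Model

`gxsreml` treats male and female observations of one quantitative trait as
the same phenotype measured in two environmental contexts. Stacking male
observations above female ones,

    y = ( y_m )   = X beta + g + e
        ( y_f )

with block fixed effects (per-sex intercepts and per-sex covariate
columns), additive genetic values `g`, and independent residuals with
sex-specific variances `se2_m`, `se2_f`. The genetic covariance between
individuals i (sex x) and j (sex z) is

    Cov(g_i, g_j) = c_xz * K[i, j]

where `K = Z Z' / M` is the genomic relationship matrix over M standardized
SNPs and

    c_mm = sg2_m,   c_ff = sg2_f,   c_mf = gamma = rho * sqrt(sg2_m sg2_f).

Equivalently, every SNP carries a pair of sex-specific effects drawn from a
zero-mean bivariate normal with variances `sg2_x / M` and correlation
`rho`; the two formulations give identical likelihoods, which the test
suite verifies on dense toys.

Per-sex heritability is `h2_x = sg2_x / (sg2_x + se2_x)`. Two constrained
model variants support the hypothesis tests:

* **rho = 1**: the cross-sex covariance is pinned at
  `sqrt(sg2_m sg2_f)` (four free parameters);
* **equal h2**: reparametrized as `(s2_m, s2_f, gamma, lambda)` with
  genetic variances `s2_x` and residual variances `lambda * s2_x`, so both
  heritabilities equal `1 / (1 + lambda)` exactly.

A sex-agnostic **univariate** comparator (one genetic, one residual
variance) uses an intercept + sex main effect + sex-by-covariate
interactions, which spans exactly the same mean structure as the bivariate
design.

Both constrained models are nested in the free model; gene-by-sex evidence
comes from likelihood-ratio tests with 1 degree of freedom (`p_rg` for
`rho != 1`, `p_h2` for `h2_m != h2_f`). The `rho = 1` null sits on the edge
of the *correlation* scale; because the fitter leaves the covariance
unconstrained (below), the null is effectively interior and the plain
chi-square(1) reference is appropriate.

## Fitting

REML fits use the **average-information (AI)** algorithm with analytic
first derivatives. Each iteration factorizes V once (LAPACK Cholesky),
forms the REML projection P explicitly, and assembles the gradient and AI
matrix from five fixed "base" matrices (the three sex blocks of K and the
two sex-diagonal indicators), so the per-iteration cost is a small multiple
of one n^3 factorization and fits converge in ~10 iterations. Steps are
Newton steps on the natural scale with step-halving; when no step along the
AI (or gradient) direction improves the objective beyond 1e-12, the fit has
reached a numerical optimum and stops. A derivative-free Nelder–Mead
restart on a transformed scale (log variances, covariance expressed as a
correlation-like ratio) is kept as a fallback for pathological starts.
Convergence requires relative objective change < 1e-8 and relative
parameter change < 1e-6 (max 200 iterations); starting values are
`sg2 = se2 = var(y_x) / 2` with `rho = 0.5`, with up to three seeded,
jittered restarts.

The AI matrix — the average of the observed and expected information — is
inverted at the optimum to give the parameter covariance; SEs of `h2_m`,
`h2_f` and `rho` follow by the delta method. In the replicate studies run
by the test suite the mean reported SEs agree with the empirical SDs to
well within 30%.

**Unconstrained genetic covariance.** The free and equal-h2 fits leave
`gamma` unconstrained (any step must keep V positive definite, which the
Cholesky line search enforces). Estimated genetic correlations can
therefore slightly exceed 1 in magnitude. This mirrors standard GREML
solvers, and matters for calibration: constraining `rho` to [-1, 1] would
censor the estimator under a true correlation of 1 and bias its mean
downward by about 0.4 sampling-SDs, manufacturing spurious "GxS" in any
mean-based null check. When a genetic variance collapses to its floor
(1e-8 of the phenotypic variance), ratios through it (h2, rho) are
unreliable; such fits carry a `boundary` flag and the calibration suite
excludes them from mean-r_g summaries (counts reported).

**Likelihood convention.** The restricted log-likelihood is reported as
`-1/2 (log|V| + log|X'V^-1 X| + y'Py)` with no additive constant; only
differences between evaluations on the same data are meaningful.

## Genomic relationship matrix

Per-SNP standardization statistics (mean and SD of reference-allele
counts) always come from a designated reference/training population and
are frozen for later use on test genotypes. The SD uses the population
form (denominator n); this is a pure rescaling absorbed by the variance
parameters. Missing calls are mean-imputed, contributing exactly 0 after
standardization, and the cross-product is divided by the number of
retained SNPs M (not per-pair non-missing counts), which keeps the GRM and
SNP-effect formulations exactly equivalent. Monomorphic columns are
dropped and reported. On-disk format is the GCTA binary triplet
(float32 lower triangle + ID text file + per-pair count file).

## Quality control

Genotype-side filters follow common GWAS practice: SNP missingness > 2%,
platform-specific missingness bias (two-sided Fisher exact, P < 1e-100),
individual missingness > 5%, Hardy–Weinberg departure (P < 1e-50, 1-df
chi-square goodness-of-fit on a designated unrelated reference subset —
at such thresholds the distinction from the exact test is immaterial, and
the dialect is documented here), and minor-allele-frequency bands
(common: MAF in (0.05, 0.5]; combined: (0.0037, 0.5]). Relatedness pruning
removes, while any pair exceeds 0.0625, the individual in the most such
pairs (ties broken by lexicographically smallest ID) — a deterministic
greedy rule; the complementary extractor returns everyone with at least
one partner above the threshold. Principal-component scores are computed
from the standardized genotype matrix with a deterministic sign convention
(largest-magnitude loading positive); the ancestry window keeps
individuals within ±3 SD of the mean on every leading component, and the
excluded set is the natural out-of-window prediction test cohort.

Phenotype-side procedures: per-sex ±3 SD outlier removal with moments
computed once on the pre-filter cohort (no iteration, since no iteration
is specified for the underlying protocol); ratio phenotypes; unit-SD
rescaling (division only, no centering); a composite score as the first
principal component of standardized measures after a 5 SD pre-exclusion;
a count-phenotype cap excluding values strictly above 15; a rank-based
inverse-normal transform `Phi^-1((rank - 0.5) / n)` with ties averaged,
optionally within sex; and distribution-matched subsampling for
categorical phenotypes (per stratum, keep the minority sex entirely and a
seeded uniform sample of equal size from the majority sex; single-sex
strata are dropped and reported). Phenotype moments use the sample SD
(ddof = 1); genotype standardization uses the population SD — each
documented where it matters, and tests pin both conventions.

## Prediction

SNP effects are back-solved as their posterior mean at the REML estimates,
`a = Cov(a, y) V^-1 (y - X beta_hat)`. Under the bivariate model each
sex's effect vector borrows information from the other sex's residuals
through the `gamma` blocks. Test individuals are scored with
`yhat_i = sum_j (s_ij - mu_j) / sigma_j * a_j` using the training
standardization statistics, sex-matched effects under the bivariate model
(a male is scored with `a_m`), and mean imputation for missing test calls.
Accuracy is the Pearson correlation between `yhat` and the phenotype
adjusted by the training-estimated fixed effects, pooled over both sexes
(per-sex accuracies are also emitted); the relative improvement is
`(acc_specific - acc_agnostic) / acc_agnostic * 100`. SNPs are matched by
identifier only — simulated pipelines share a .bim, and allele-flip
harmonization is out of scope.

## Synthetic cohorts

The generator draws per-SNP allele frequencies uniformly on
[maf_low, maf_high], genotypes as two independent Bernoulli(p_j) draws (no
linkage disequilibrium), a causal subset with bivariate-normal effect
pairs scaled so the total genetic variance per sex equals `sg2_x` exactly
(effects act on genotypes standardized by the *true* frequency), an
age-like covariate with per-sex coefficients, and sex-specific normal
residuals. Sex is assigned by counts (first `n_male` individuals male) for
reproducibility. Missingness is applied after the complete genotypes are
drawn, so simulated genetic values are exact even under missing data. One
integer seed drives two documented streams (frequencies/genotypes/missing
mask, then causal selection/effects/covariates/residuals); outputs are
bit-reproducible. Default truth: 1000 + 1000 individuals, 2000 SNPs
(500 causal), MAF 0.05–0.5, `h2_m = 0.3`, `h2_f = 0.4`, `rho = 0.7`,
unit phenotypic variance per sex.

Deliberately absent from the generator, hence untested against real data:
linkage disequilibrium, X-chromosome effects, assortative mating,
ascertainment and enrolment bias, and population stratification. Passing
simulation suites therefore demonstrate correctness of the estimator and
its calibration under the model's own assumptions, not robustness to
those real-data features.

## Replicate-study sizes

The test suite's simulation studies use desk-scale sizes chosen to keep
each study's assertion statistically meaningful on a single CPU:

* likelihood-oracle equivalence: random instances with n <= 50, 50
  parameter draws across all four model variants, tolerance 1e-8;
* parameter recovery: truth `h2_m = 0.3`, `h2_f = 0.4`, `rho = 0.7` at
  n = 1000 (500/500), M = 700 (200 causal), with 3-SE coverage checked
  over 20 replicates;
* SE validity: the same design over 100 replicates, reported SEs vs
  empirical SDs within 30%;
* LRT null calibration: `rho = 1`, equal `h2 = 0.3`, n = 800 (400/400),
  200 replicates, exact binomial 95% interval around the 0.05 rate;
* distribution-robustness null: `rho = 1` with a 2x-scaled female trait
  and unequal heritabilities (0.35 vs 0.5), n = 1200, 100 replicates,
  mean r_g within 3 SEM of 1;
* prediction ordering: `rho = 0.5`, `h2 = 0.35` both sexes, n = 1600 with
  a 25% test split, 20 replicates per architecture.

## Known limitations

* Dense O(n^3) algebra bounds practical cohorts to a few tens of
  thousands of individuals; no low-rank or distributed path is provided.
* The 1-df chi-square LRT shows mild small-sample upper-tail inflation
  for the equal-h2 test at n in the hundreds (empirical rate ~0.07-0.08
  at alpha = 0.05 around n = 600-800), vanishing with n; the reference
  distribution is asymptotic.
* Heritability estimates are on the observed scale; no liability-scale
  transformation is offered for categorical phenotypes.
* The platform-bias filter supports exactly two platforms.
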