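# gxsreml

Sex-stratified bivariate GREML: estimation of sex-specific heritabilities
and the cross-sex genetic correlation of a quantitative trait, with
likelihood-ratio tests for gene-by-sex (GxS) interaction and sex-specific
vs sex-agnostic genomic prediction.

## The problem

Many human complex traits differ between men and women. Two signatures of
a sex-specific genetic architecture are (i) unequal heritabilities,
`h2_m != h2_f`, and (ii) a cross-sex genetic correlation below one,
`r_g < 1`, meaning autosomal effects are not simply proportional between
the sexes. `gxsreml` estimates both from individual-level SNP data by
treating male and female observations as one phenotype measured in two
environmental contexts:

    y = (y_m; y_f) = X beta + g + e,
    Cov(g_i, g_j) = c_xz K[i,j],   c_mm = sg2_m, c_ff = sg2_f,
                                   c_mf = r_g sqrt(sg2_m sg2_f)

with `K` the genomic relationship matrix over standardized SNPs,
sex-specific residual variances, and `h2_x = sg2_x / (sg2_x + se2_x)`.
Restricted maximum likelihood (average-information REML) fits the free
model and two constrained variants (`r_g = 1`; equal heritabilities via a
`lambda` reparametrization), and 1-df likelihood-ratio tests give P values
for `r_g != 1` and `h2_m != h2_f`. Per-SNP effects back-solved from the
fitted models (GBLUP posterior means) yield sex-specific and sex-agnostic
polygenic predictors whose accuracies can be compared on a held-out
cohort.

Because individual-level biobank data cannot ship with a repository, the
package includes a first-class synthetic-cohort generator with a known
sex-specific architecture (sample sizes, MAF spectrum, per-sex genetic
and residual variances, cross-sex effect correlation, covariates,
missingness), so the whole pipeline — QC, GRM, REML, LRTs, prediction —
is exercisable and testable without any download. It is aimed at
quantitative geneticists who want a transparent, tested reference
implementation of the sex-stratified GREML workflow at desk scale.

## Worked example

Simulate a cohort of 500 men and 500 women typed at 800 SNPs (250 causal)
with true `h2_m = 0.3`, `h2_f = 0.4`, `r_g = 0.7`, run QC, build the GRM,
fit all model variants and compare predictors:

```python
import json
from gxsreml.pipeline import RunConfig, run_pipeline
from gxsreml.simgen import GxsTruth

cfg = RunConfig(
    truth=GxsTruth(n_male=500, n_female=500, n_snps=800, n_causal=250,
                   sigma2_g_m=0.3, sigma2_e_m=0.7,
                   sigma2_g_f=0.4, sigma2_e_f=0.6,
                   rho=0.7, seed=1),
    out_dir="demo",
)
print(json.dumps(run_pipeline(cfg), indent=2, sort_keys=True))
```

prints (abridged):

```json
{
  "gxs": {
    "h2_m": 0.1957, "se_h2_m": 0.0849,
    "h2_f": 0.3802, "se_h2_f": 0.0826,
    "rg": 1.0230,  "se_rg": 0.2994,
    "p_rg": 0.9397, "p_h2": 0.1286
  },
  "prediction": {
    "accuracy_specific": 0.2525,
    "accuracy_agnostic": 0.2653,
    "relative_improvement_pct": -4.80
  }
}
```

Read: the male heritability estimate is 0.20 (SE 0.08) against a truth of
0.3 and the genetic correlation estimate is 1.02 (SE 0.30) against a truth
of 0.7 — at n = 1000 a single cohort carries limited information, and both
true values sit within ~1.2 reported SEs of their estimates (note an
unconstrained `r_g` estimate may exceed 1). Neither LRT is significant
here, and accordingly the sex-specific predictor does not beat the
sex-agnostic one on this replicate. Power to detect `r_g != 1` and a
consistent prediction advantage emerge at larger n and in replicate
averages, which is what the test suite measures (e.g. mean sex-specific
accuracy exceeds the sex-agnostic mean over 20 replicates at n = 1600
under `r_g = 0.5`). The same run writes `demo/gxs_table.tsv` (one row of
estimates, SEs and P values), fitted parameters, SNP-effect TSVs,
predictions and a manifest.

The same pipeline is scriptable from the shell:

```bash
gxsreml pipeline -c config.yaml -o demo        # or stage by stage:
gxsreml simulate -c config.yaml -o demo
gxsreml qc -c config.yaml -o demo
gxsreml grm -c config.yaml -o demo
gxsreml fit -c config.yaml -o demo
gxsreml calibrate -c grid.yaml -r 200 -o calib
gxsreml predict-experiment -c grid.yaml -r 20 -o predexp
```

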