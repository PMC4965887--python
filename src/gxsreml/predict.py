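"""GBLUP SNP-effect back-solving and sex-specific genomic prediction.

SNP effects are recovered as their posterior mean given the phenotypes with
variance and fixed-effect parameters fixed at the REML estimates:

    a = Cov(a, y) V^-1 (y - X beta_hat)

For the sex-agnostic model every SNP has effect variance sg2/M shared by
both sexes, so a = (sg2/M) Z' V^-1 r.  For the bivariate model each sex has
its own effect vector and the cross-sex covariance (the rho term) lets each
sex's effects borrow information from the other sex's residuals:

    a_m = (1/M) [ sg2_m Z_m' r*_m + gamma Z_f' r*_f ],   r* = V^-1 r

Test individuals are scored with the prediction equation
yhat_i = sum_j (s_ij - mu_j)/sigma_j * a_j using the *training* population's
standardization statistics (missing test calls contribute 0), with the
sex-matched vector under the bivariate model.  Accuracy is the Pearson
correlation between yhat and the phenotype adjusted for fixed effects using
the training-estimated coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grm import Grm
from .simgen import MISSING, GenotypeMatrix, SexedCohort
from .reml import GxsProblem, RemlError, RemlFit, _Evaluator, design_matrix


@dataclass
class SnpEffectSet:
    """Back-solved per-SNP effects plus frozen training standardization."""

    snp_ids: np.ndarray
    effects: dict[str, np.ndarray]  # {"shared": a} or {"m": a_m, "f": a_f}
    mu: np.ndarray
    sd: np.ndarray
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = len(self.snp_ids)
        for key, a in self.effects.items():
            if len(a) != m:
                raise ValueError(f"effect vector '{key}' length != SNP count")
        if len(self.mu) != m or len(self.sd) != m:
            raise ValueError("standardization statistics must match SNP count")

    @property
    def is_sex_specific(self) -> bool:
        return "shared" not in self.effects

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"snp_id": self.snp_ids, "mu": self.mu, "sd": self.sd})
        for key, a in self.effects.items():
            df[f"effect_{key}"] = a
        return df

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "SnpEffectSet":
        df = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
        eff = {
            c.removeprefix("effect_"): df[c].to_numpy(float)
            for c in df.columns
            if c.startswith("effect_")
        }
        return cls(
            snp_ids=df["snp_id"].to_numpy(dtype=object),
            effects=eff,
            mu=df["mu"].to_numpy(float),
            sd=df["sd"].to_numpy(float),
        )


@dataclass
class PredictionOutcome:
    """Accuracy of the sex-specific vs sex-agnostic predictors on one test set."""

    accuracy_specific: float
    accuracy_agnostic: float
    relative_improvement_pct: float
    per_sex_specific: dict[str, float] = field(default_factory=dict)
    per_sex_agnostic: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy_specific": float(self.accuracy_specific),
            "accuracy_agnostic": float(self.accuracy_agnostic),
            "relative_improvement_pct": float(self.relative_improvement_pct),
            "per_sex_specific": {k: float(v) for k, v in self.per_sex_specific.items()},
            "per_sex_agnostic": {k: float(v) for k, v in self.per_sex_agnostic.items()},
        }


def blup_effects(
    fit: RemlFit,
    grm: Grm,
    cohort: SexedCohort,
    z: np.ndarray,
    geno_std: GenotypeMatrix,
) -> SnpEffectSet:
    """Posterior-mean SNP effects from a converged fit.

    ``z`` is the standardized training genotype matrix in ``cohort`` row
    order; ``geno_std`` carries the SNP ids and the frozen mu/sigma of the
    training population (as produced by :func:`gxsreml.grm.standardize`).
    """
    if not fit.converged:
        raise RemlError("refusing to back-solve effects from an unconverged fit")
    if geno_std.ref_allele_mean is None or geno_std.ref_allele_sd is None:
        raise ValueError("geno_std must carry training standardization statistics")
    if z.shape != (cohort.n, geno_std.m):
        raise ValueError("z shape must be (n_cohort, M)")

    univariate = fit.params.parametrization == "univariate"
    prob = GxsProblem(grm, cohort, univariate_design=univariate)
    ev = _Evaluator(prob)
    p = fit.params
    c = np.array([p.sigma2_g_m, p.sigma2_g_f, p.gamma, p.sigma2_e_m, p.sigma2_e_f])
    state = ev.full_state(c)
    if state is None:
        raise RemlError("covariance matrix singular at the fitted parameters")
    u = state[4]  # V^-1 (y - X beta_hat)
    zo = z[prob.cohort_order]
    m = geno_std.m
    nm = prob.nm
    if univariate:
        a = (p.sigma2_g_m / m) * (zo.T @ u)
        effects = {"shared": a}
    else:
        zm_u = zo[:nm].T @ u[:nm]
        zf_u = zo[nm:].T @ u[nm:]
        gamma = p.gamma
        effects = {
            "m": (p.sigma2_g_m * zm_u + gamma * zf_u) / m,
            "f": (gamma * zm_u + p.sigma2_g_f * zf_u) / m,
        }
    return SnpEffectSet(
        snp_ids=geno_std.snp_ids.copy(),
        effects=effects,
        mu=geno_std.ref_allele_mean.copy(),
        sd=geno_std.ref_allele_sd.copy(),
        source={"parametrization": p.parametrization, "n_snps": m},
    )


def score(
    effects: SnpEffectSet,
    test_geno: GenotypeMatrix,
    sex: np.ndarray,
) -> np.ndarray:
    """Predicted additive genetic values for test individuals.

    SNPs are matched by identifier (strict intersection); test genotypes are
    standardized with the training mu/sigma and missing calls contribute 0.
    """
    eff_pos = {s: j for j, s in enumerate(effects.snp_ids)}
    test_j, eff_j = [], []
    for jt, s in enumerate(test_geno.snp_ids):
        je = eff_pos.get(s)
        if je is not None:
            test_j.append(jt)
            eff_j.append(je)
    if not test_j:
        raise ValueError("no SNP overlap between effect set and test genotypes")
    if len(test_j) < len(effects.snp_ids):
        import warnings

        warnings.warn(
            f"only {len(test_j)} of {len(effects.snp_ids)} effect SNPs present "
            "in the test genotypes",
            stacklevel=2,
        )
    test_j = np.array(test_j)
    eff_j = np.array(eff_j)
    counts = test_geno.counts[:, test_j].astype(float)
    miss = counts == MISSING
    zt = (counts - effects.mu[eff_j]) / effects.sd[eff_j]
    zt[miss] = 0.0

    sex = np.asarray(sex)
    if not effects.is_sex_specific:
        return zt @ effects.effects["shared"][eff_j]
    yhat = np.empty(test_geno.n)
    male = sex == 1
    yhat[male] = zt[male] @ effects.effects["m"][eff_j]
    yhat[~male] = zt[~male] @ effects.effects["f"][eff_j]
    return yhat


def adjusted_phenotype(cohort: SexedCohort, fit: RemlFit) -> np.ndarray:
    """y - X beta_hat with beta_hat from the training fit."""
    univariate = fit.params.parametrization == "univariate"
    x, names = design_matrix(cohort.sex, cohort.covariates, univariate)
    if names != fit.beta_names:
        raise ValueError(
            "test covariate columns do not match the training design "
            f"({names} vs {fit.beta_names})"
        )
    return cohort.y - x @ fit.beta


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def accuracy(
    predicted: np.ndarray, cohort: SexedCohort, fit: RemlFit
) -> tuple[float, dict[str, float]]:
    """Pooled and per-sex Pearson correlation with the adjusted phenotype."""
    adj = adjusted_phenotype(cohort, fit)
    pooled = _pearson(predicted, adj)
    per_sex = {}
    for lab, rows in (("m", cohort.is_male), ("f", ~cohort.is_male)):
        if rows.sum() >= 3:
            per_sex[lab] = _pearson(predicted[rows], adj[rows])
    return pooled, per_sex


def prediction_outcome(
    yhat_specific: np.ndarray,
    yhat_agnostic: np.ndarray,
    cohort: SexedCohort,
    fit_specific: RemlFit,
    fit_agnostic: RemlFit,
) -> PredictionOutcome:
    acc_s, per_s = accuracy(yhat_specific, cohort, fit_specific)
    acc_a, per_a = accuracy(yhat_agnostic, cohort, fit_agnostic)
    rel = (
        float("nan")
        if acc_a == 0 or np.isnan(acc_a)
        else (acc_s - acc_a) / abs(acc_a) * 100.0
    )
    return PredictionOutcome(
        accuracy_specific=acc_s,
        accuracy_agnostic=acc_a,
        relative_improvement_pct=rel,
        per_sex_specific=per_s,
        per_sex_agnostic=per_a,
    )


def write_predictions(
    path: str | Path,
    cohort: SexedCohort,
    yhat_bivariate: np.ndarray | None = None,
    yhat_univariate: np.ndarray | None = None,
) -> None:
    df = pd.DataFrame({"FID": cohort.ids, "IID": cohort.ids, "sex": cohort.sex})
    if yhat_univariate is not None:
        df["yhat_univariate"] = yhat_univariate
    if yhat_bivariate is not None:
        df["yhat_bivariate"] = yhat_bivariate
    df.to_csv(path, sep="\t", index=False)
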