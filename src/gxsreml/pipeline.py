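"""End-to-end orchestration: simulate -> qc -> grm -> reml -> predict.

Each stage reads and writes files inside one output directory so stages are
independently resumable and testable; a manifest records the configuration
hash, seed and package version for every run.  Replicate suites (the LRT
calibration grid and the prediction-improvement experiment) live here too;
replicate r of a suite uses seed ``base_seed + r``.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import grm as grm_mod
from . import plinkio, predict, qc, reml
from .simgen import (
    GxsTruth,
    simulate_genotypes,
    simulate_phenotypes,
    split_train_test,
)


@dataclass
class QcThresholds:
    """QC thresholds; the defaults are the pipeline's reference settings."""

    snp_missingness: float = 0.02
    platform_bias_p: float = 1e-100
    individual_missingness: float = 0.05
    hwe_p: float = 1e-50
    maf_low: float = 0.05
    maf_high: float = 0.5
    relatedness: float = 0.0625
    outlier_sd: float = 3.0
    composite_exclusion_sd: float = 5.0
    count_cap: int = 15
    ancestry_sd: float = 3.0
    n_pcs: int = 20


@dataclass
class RunConfig:
    truth: GxsTruth = field(default_factory=GxsTruth)
    thresholds: QcThresholds = field(default_factory=QcThresholds)
    reml: reml.RemlOptions = field(default_factory=reml.RemlOptions)
    stages: tuple[str, ...] = ("simulate", "qc", "grm", "fit", "predict")
    test_fraction: float = 0.25
    split_seed: int = 0
    n_pcs_fixed_effects: int = 0  # leading PCs added as covariates (0 = none)
    out_dir: str = "gxs_run"

    def to_dict(self) -> dict:
        return {
            "truth": self.truth.to_dict(),
            "thresholds": vars(self.thresholds).copy(),
            "reml": vars(self.reml).copy(),
            "stages": list(self.stages),
            "test_fraction": self.test_fraction,
            "split_seed": self.split_seed,
            "n_pcs_fixed_effects": self.n_pcs_fixed_effects,
            "out_dir": str(self.out_dir),
        }


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_json(path: Path, obj: dict) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _manifest(out: Path, config: RunConfig, artifacts: list[str]) -> None:
    _write_json(
        out / "manifest.json",
        {
            "config": config.to_dict(),
            "config_hash": config_hash(config),
            "artifacts": sorted(artifacts),
            "gxsreml_version": __version__,
            "python": platform.python_version(),
        },
    )


def run_pipeline(config: RunConfig, force: bool = False) -> dict:
    """Execute the enabled stages in order; returns the summary dict.

    Stage outputs are files under ``config.out_dir``; a stage whose outputs
    already exist is skipped unless ``force``.  A stage whose inputs are
    missing raises an error naming the stage that must run first.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    summary: dict = {}

    def needs(path: Path, producer: str) -> Path:
        if not path.exists():
            raise FileNotFoundError(
                f"missing artifact {path.name}; run the '{producer}' stage first"
            )
        return path

    if "simulate" in config.stages:
        if force or not (out / "geno.bed").exists():
            geno = simulate_genotypes(config.truth)
            cohort = simulate_phenotypes(geno, config.truth)
            plinkio.write_plink(geno, out / "geno", sex=cohort.sex)
            plinkio.write_phenotypes(cohort, out / "phenotypes.tsv")
            plinkio.write_truth(config.truth, out / "truth.json")
        artifacts += ["geno.bed", "geno.bim", "geno.fam", "phenotypes.tsv", "truth.json"]

    if "qc" in config.stages:
        needs(out / "geno.bed", "simulate")
        geno = plinkio.read_plink(out / "geno")
        cohort = plinkio.read_phenotypes(out / "phenotypes.tsv")
        th = config.thresholds
        reports = []
        geno, rep = qc.filter_snp_missingness(geno, th.snp_missingness)
        reports.append(rep)
        geno, rep = qc.filter_individual_missingness(geno, th.individual_missingness)
        reports.append(rep)
        geno, rep = qc.hwe_filter(geno, th.hwe_p)
        reports.append(rep)
        geno, rep = qc.maf_band_filter(geno, th.maf_low, th.maf_high)
        reports.append(rep)
        keep = np.isin(cohort.ids, geno.ids)
        cohort = cohort.subset(keep)
        cohort, rep = qc.per_sex_outlier_removal(cohort, th.outlier_sd)
        reports.append(rep)
        geno = geno.subset_individuals(np.isin(geno.ids, cohort.ids))
        if config.n_pcs_fixed_effects > 0:
            # leading genomic PCs as fixed-effect covariates (population
            # structure adjustment)
            pcs = qc.compute_pcs(geno, k=config.n_pcs_fixed_effects)
            for k in range(pcs.shape[1]):
                cohort.covariates[f"pc{k + 1}"] = pcs[:, k]
        plinkio.write_plink(geno, out / "geno_qc", sex=cohort.sex)
        plinkio.write_phenotypes(cohort, out / "phenotypes_qc.tsv")
        _write_json(out / "qc_report.json", {"stages": [r.to_dict() for r in reports]})
        artifacts += ["geno_qc.bed", "phenotypes_qc.tsv", "qc_report.json"]

    if "grm" in config.stages:
        needs(out / "geno_qc.bed", "qc")
        geno = plinkio.read_plink(out / "geno_qc")
        g, _ = grm_mod.grm_from_genotypes(geno)
        grm_mod.write_grm(g, out / "cohort")
        artifacts += ["cohort.grm.bin", "cohort.grm.id", "cohort.grm.N.bin"]

    if "fit" in config.stages:
        needs(out / "cohort.grm.bin", "grm")
        g = grm_mod.read_grm(out / "cohort")
        cohort = plinkio.read_phenotypes(out / "phenotypes_qc.tsv")
        result = reml.gxs_report(g, cohort, options=config.reml)
        _write_json(out / "gxs_result.json", result.to_dict())
        _write_json(
            out / "fits.json",
            {
                "free": result.fit_free.to_dict(),
                "rho1": result.fit_rho1.to_dict(),
                "equal_h2": result.fit_equal_h2.to_dict(),
            },
        )
        gxs_table(result).to_csv(out / "gxs_table.tsv", sep="\t", index=False)
        summary["gxs"] = result.to_dict()
        artifacts += ["gxs_result.json", "fits.json", "gxs_table.tsv"]

    if "predict" in config.stages:
        needs(out / "geno_qc.bed", "qc")
        geno = plinkio.read_plink(out / "geno_qc")
        cohort = plinkio.read_phenotypes(out / "phenotypes_qc.tsv")
        outcome = prediction_run(
            geno,
            cohort,
            test_fraction=config.test_fraction,
            split_seed=config.split_seed,
            options=config.reml,
            out_dir=out,
        )
        summary["prediction"] = outcome.to_dict()
        artifacts += ["predictions.tsv", "prediction_summary.json"]

    _write_json(out / "summary.json", summary)
    artifacts.append("summary.json")
    _manifest(out, config, artifacts)
    return summary


def gxs_table(result: reml.GxsResult) -> pd.DataFrame:
    """Human-readable single-row table: estimates, SEs and both LRT P values."""
    return pd.DataFrame(
        [
            {
                "h2_m": result.h2_m,
                "h2_m_se": result.se_h2_m,
                "h2_f": result.h2_f,
                "h2_f_se": result.se_h2_f,
                "rg": result.rg,
                "rg_se": result.se_rg,
                "p_rg_ne_1": result.p_rg,
                "p_h2m_ne_h2f": result.p_h2,
            }
        ]
    )


def prediction_run(
    geno,
    cohort,
    test_fraction: float = 0.25,
    split_seed: int = 0,
    options: reml.RemlOptions | None = None,
    out_dir: Path | None = None,
) -> predict.PredictionOutcome:
    """Train/test split, both models, BLUP effects, scoring, accuracy."""
    (train_c, train_g), (test_c, test_g) = split_train_test(
        cohort, geno, test_fraction, split_seed
    )
    z, geno_std = grm_mod.standardize(train_g)
    g = grm_mod.Grm(
        ids=geno_std.ids, matrix=grm_mod.compute_grm(z), n_snps_used=geno_std.m
    )
    fit_biv = reml.fit_bivariate(g, train_c, options=options)
    fit_uni = reml.fit_univariate(g, train_c, options=options)
    eff_biv = predict.blup_effects(fit_biv, g, train_c, z, geno_std)
    eff_uni = predict.blup_effects(fit_uni, g, train_c, z, geno_std)
    yhat_biv = predict.score(eff_biv, test_g, test_c.sex)
    yhat_uni = predict.score(eff_uni, test_g, test_c.sex)
    outcome = predict.prediction_outcome(yhat_biv, yhat_uni, test_c, fit_biv, fit_uni)
    if out_dir is not None:
        predict.write_predictions(
            out_dir / "predictions.tsv", test_c, yhat_biv, yhat_uni
        )
        eff_biv.write(out_dir / "effects_bivariate.tsv")
        eff_uni.write(out_dir / "effects_univariate.tsv")
        _write_json(out_dir / "prediction_summary.json", outcome.to_dict())
    return outcome


# ---------------------------------------------------------------------------
# replicate suites


def _replicate_truth(truth: GxsTruth, seed: int) -> GxsTruth:
    d = truth.to_dict()
    d["seed"] = seed
    return GxsTruth.from_dict(d)


def run_calibration(
    truths: list[GxsTruth],
    n_replicates: int,
    base_seed: int = 0,
    alpha: float = 0.05,
    options: reml.RemlOptions | None = None,
) -> pd.DataFrame:
    """Null-calibration grid: per truth, gxs_report over seeded replicates.

    Tabulates the rejection rates of both LRTs at ``alpha``, the mean r_g
    estimate (with its SE of the mean) and the mean heritability bias.
    Replicates that fail to converge are excluded and counted.
    """
    rows = []
    for t_idx, truth in enumerate(truths):
        stats_rows = []
        failures = 0
        for r in range(n_replicates):
            t = _replicate_truth(truth, base_seed + r)
            geno = simulate_genotypes(t)
            cohort = simulate_phenotypes(geno, t)
            z, gs = grm_mod.standardize(geno)
            g = grm_mod.Grm(ids=gs.ids, matrix=grm_mod.compute_grm(z), n_snps_used=gs.m)
            try:
                res = reml.gxs_report(g, cohort, options=options)
            except reml.RemlError:
                failures += 1
                continue
            stats_rows.append(
                {
                    "p_rg": res.p_rg,
                    "p_h2": res.p_h2,
                    "rg": res.rg,
                    "h2_m": res.h2_m,
                    "h2_f": res.h2_f,
                    "boundary": res.fit_free.boundary,
                }
            )
        df = pd.DataFrame(stats_rows)
        n_ok = len(df)
        rows.append(
            {
                "truth_index": t_idx,
                "n_male": truth.n_male,
                "n_female": truth.n_female,
                "rho_true": truth.rho,
                "h2_m_true": truth.h2_m,
                "h2_f_true": truth.h2_f,
                "n_replicates": n_ok,
                "n_failures": failures,
                "reject_rate_rg": float((df["p_rg"] < alpha).mean()) if n_ok else np.nan,
                "reject_rate_h2": float((df["p_h2"] < alpha).mean()) if n_ok else np.nan,
                # rho is a ratio of variance estimates; replicates where a
                # variance collapsed to its floor are excluded from its mean
                "n_boundary": int(df["boundary"].sum()) if n_ok else 0,
                "mean_rg": float(df.loc[~df["boundary"], "rg"].mean())
                if n_ok and (~df["boundary"]).any()
                else np.nan,
                "sem_rg": float(
                    df.loc[~df["boundary"], "rg"].std(ddof=1)
                    / np.sqrt((~df["boundary"]).sum())
                )
                if n_ok and (~df["boundary"]).sum() > 1
                else np.nan,
                "bias_h2_m": float(df["h2_m"].mean() - truth.h2_m) if n_ok else np.nan,
                "bias_h2_f": float(df["h2_f"].mean() - truth.h2_f) if n_ok else np.nan,
            }
        )
    return pd.DataFrame(rows)


def run_prediction_experiment(
    truths: list[GxsTruth],
    n_replicates: int,
    test_fraction: float = 0.25,
    base_seed: int = 0,
    options: reml.RemlOptions | None = None,
) -> pd.DataFrame:
    """Replicate train/test splits per truth; mean and spread of improvement."""
    rows = []
    for t_idx, truth in enumerate(truths):
        improvements, acc_s, acc_a = [], [], []
        for r in range(n_replicates):
            t = _replicate_truth(truth, base_seed + r)
            geno = simulate_genotypes(t)
            cohort = simulate_phenotypes(geno, t)
            outcome = prediction_run(
                geno,
                cohort,
                test_fraction=test_fraction,
                split_seed=base_seed + r,
                options=options,
            )
            improvements.append(outcome.relative_improvement_pct)
            acc_s.append(outcome.accuracy_specific)
            acc_a.append(outcome.accuracy_agnostic)
        imp = np.asarray(improvements)
        rows.append(
            {
                "truth_index": t_idx,
                "rho_true": truth.rho,
                "h2_m_true": truth.h2_m,
                "h2_f_true": truth.h2_f,
                "n_replicates": len(imp),
                "mean_accuracy_specific": float(np.mean(acc_s)),
                "mean_accuracy_agnostic": float(np.mean(acc_a)),
                "mean_improvement_pct": float(np.mean(imp)),
                "sd_improvement_pct": float(np.std(imp, ddof=1)) if len(imp) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)
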