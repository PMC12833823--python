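"""End-to-end experiment drivers with one master seed and a manifest.

Two composite experiments mirror the study design on synthetic data:

* ``run_benchmark`` — generate the 10-class patch benchmark, train the
  compact classifier, and evaluate held-out per-class accuracy and
  Cohen's kappa;
* ``run_prognostic_study`` — simulate six survival cohorts (one
  TCGA-like discovery cohort plus five external cohorts), run per-cohort
  univariate Cox models on MTSR, pool the log-HRs through the
  heterogeneity-gated meta-analysis, fit the multivariate MTSR + N-stage
  model on the discovery cohort, and derive the nomogram, calibration,
  decision-curve, time-dependent AUC, and cutpoint-stratified
  Kaplan-Meier reports.

A single master seed fans out to per-stage seeds through
``numpy.random.SeedSequence`` spawning; the manifest records every
derived seed so any stage can be reproduced in isolation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classifier import ClassifierConfig, evaluate, predict_patches, train_classifier
from .meta import egger_test, meta_pool
from .simulate import SurvivalCohortSpec, gen_survival_cohorts
from .survival import (
    build_nomogram,
    calibration_bootstrap,
    concordance_index,
    decision_curve,
    fit_cox,
    km_logrank,
    maxstat_cutpoint,
    predict_nomogram,
    schoenfeld_test,
    time_dependent_auc,
)
from .synthetic import CLASS_NAMES, TexturePalette, gen_patch_dataset


@dataclass(frozen=True)
class PipelineConfig:
    master_seed: int = 0
    # patch benchmark
    difficulty: float = 0.3
    n_train_per_class: int = 600
    n_test_per_class: int = 200
    patch_size: int = 64
    epochs: int = 4
    batch_size: int = 160
    learning_rate: float = 0.01
    lr_decay_per_batch: float = 0.9999
    # prognostic study
    n_cohorts: int = 6
    cohort_size: int = 300
    beta_mtsr: float = float(np.log(1.5) / 10.0)  # log-HR per MTSR percentage point
    beta_nstage: float = float(np.log(1.8))
    baseline_hazard: float = 0.05
    censoring_rate: float = 0.03
    heterogeneity_tau2: float = 0.0
    cutpoint_strategy: str = "maxstat"  # or "median"
    horizons: tuple[float, ...] = (1.0, 3.0, 5.0)
    i2_gate: float = 0.25
    qp_gate: float = 0.05
    n_perm: int = 199
    calibration_boot: int = 200


def _stage_seeds(master_seed: int, names: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(master_seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def _manifest(config: PipelineConfig, seeds: dict[str, int]) -> dict:
    return {"version": __version__, "config": asdict(config), "seeds": seeds}


def run_benchmark(config: PipelineConfig = PipelineConfig(), out_dir: str | Path | None = None) -> dict:
    """Patch benchmark: generate, train, evaluate. Returns the report bundle."""
    seeds = _stage_seeds(config.master_seed, ["train_data", "test_data", "model"])
    palette = TexturePalette(difficulty=config.difficulty)
    x_train, y_train = gen_patch_dataset(
        palette, config.n_train_per_class, config.patch_size, seeds["train_data"]
    )
    x_test, y_test = gen_patch_dataset(
        palette, config.n_test_per_class, config.patch_size, seeds["test_data"]
    )
    clf_config = ClassifierConfig(
        input_size=config.patch_size,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        lr_decay_per_batch=config.lr_decay_per_batch,
        epochs=config.epochs,
        seed=seeds["model"],
    )
    model = train_classifier(x_train, y_train, clf_config)
    pred, _ = predict_patches(model, x_test)
    cm = evaluate(y_test, pred)
    report = {
        "manifest": _manifest(config, seeds),
        "training_history": model.history,
        "confusion_matrix": cm.counts.tolist(),
        "class_names": list(CLASS_NAMES),
        "per_class_accuracy": {
            c: float(a) for c, a in zip(CLASS_NAMES, cm.per_class_accuracy)
        },
        "min_per_class_accuracy": float(np.nanmin(cm.per_class_accuracy)),
        "overall_accuracy": cm.accuracy,
        "kappa": cm.kappa,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "benchmark_report.json").write_text(json.dumps(report, indent=2))
    return report


def run_prognostic_study(config: PipelineConfig = PipelineConfig(), out_dir: str | Path | None = None) -> dict:
    """Six-cohort MTSR prognostic evaluation. Returns the report bundle."""
    seed_names = [f"cohort_{i}" for i in range(config.n_cohorts)] + [
        "cutpoint", "calibration"
    ]
    seeds = _stage_seeds(config.master_seed, seed_names)
    specs = [
        SurvivalCohortSpec(
            n_subjects=config.cohort_size,
            baseline_hazard=config.baseline_hazard,
            beta_mtsr=config.beta_mtsr,
            beta_nstage=config.beta_nstage,
            censoring_rate=config.censoring_rate,
            heterogeneity_tau2=config.heterogeneity_tau2,
            seed=seeds[f"cohort_{i}"],
        )
        for i in range(config.n_cohorts)
    ]
    cohorts = gen_survival_cohorts(specs)

    # stage 1: per-cohort univariate Cox on MTSR
    per_cohort = []
    for i, df in enumerate(cohorts):
        fit = fit_cox(df, ["mtsr"])
        per_cohort.append(
            {"cohort": f"cohort_{i}", "loghr": float(fit.beta["mtsr"]),
             "se": float(fit.se["mtsr"]), "hr": float(fit.hr["mtsr"]),
             "n": len(df), "events": int(df["event"].sum())}
        )
    theta = np.array([c["loghr"] for c in per_cohort])
    se = np.array([c["se"] for c in per_cohort])

    # stage 2: heterogeneity-gated pooling + small-study bias check
    pooled = meta_pool(theta, se, config.i2_gate, config.qp_gate)
    egger = egger_test(theta, se)

    # discovery cohort: multivariate model, nomogram, calibration, DCA, td-AUC
    disc = cohorts[0]
    multi = fit_cox(disc, ["mtsr", "nstage"])
    nomogram = build_nomogram(multi, list(config.horizons))
    nomo_surv = predict_nomogram(nomogram, disc)
    calib = calibration_bootstrap(
        multi, list(config.horizons), n_boot=config.calibration_boot,
        seed=seeds["calibration"],
    )
    lp = multi.linear_predictor(disc)
    cindex = concordance_index(disc, lp)
    td_auc = time_dependent_auc(disc, lp, list(config.horizons))
    dca = {}
    for t in config.horizons:
        risk = 1.0 - nomo_surv[t].to_numpy()
        dca[t] = decision_curve(disc, {"nomogram": risk}, t)
    ph = schoenfeld_test(multi)

    # cutpoint stratification + KM on the pooled external data
    combined = pd.concat(cohorts[1:], ignore_index=True)
    if config.cutpoint_strategy == "median":
        cutoff = float(combined["mtsr"].median())
        cut_info = {"strategy": "median", "cutoff": cutoff}
    else:
        cp = maxstat_cutpoint(
            combined, "mtsr", n_perm=config.n_perm, seed=seeds["cutpoint"]
        )
        cutoff = cp.cutoff
        cut_info = {"strategy": "maxstat", "cutoff": cutoff,
                    "statistic": cp.statistic, "p_value": cp.p_value}
    km = km_logrank(combined, combined["mtsr"] > cutoff)

    report = {
        "manifest": _manifest(config, seeds),
        "per_cohort": per_cohort,
        "meta": {
            "pooled_loghr": pooled.pooled,
            "pooled_hr": float(np.exp(pooled.pooled)),
            "ci_loghr": list(pooled.ci),
            "ci_hr": [float(np.exp(c)) for c in pooled.ci],
            "q": pooled.q, "q_p": pooled.q_p, "i2": pooled.i2, "tau2": pooled.tau2,
            "chosen_model": pooled.chosen_model,
            "egger": egger,
        },
        "multivariate": {
            "hr": {c: float(multi.hr[c]) for c in multi.covariates},
            "ci": {c: [float(multi.ci_lower[c]), float(multi.ci_upper[c])]
                   for c in multi.covariates},
            "p": {c: float(multi.p[c]) for c in multi.covariates},
            "c_index": cindex,
        },
        "td_auc": {str(t): v for t, v in td_auc.items()},
        "calibration": {
            "slope_apparent": calib["slope_apparent"],
            "slope_corrected": calib["slope_corrected"],
            "table": calib["table"].to_dict(orient="records"),
        },
        "proportional_hazards": ph.to_dict(orient="records"),
        "cutpoint": cut_info,
        "km_logrank": {"chi2": km.chi2, "p": km.p_value},
        "decision_curve": {
            str(t): d.to_dict(orient="records") for t, d in dca.items()
        },
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "prognostic_report.json").write_text(json.dumps(report, indent=2))
    return report
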