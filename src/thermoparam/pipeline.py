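"""End-to-end study pipeline.

``run_pipeline`` executes the full analysis pathway on a thermogram matrix
plus clinical table: preprocessing → 20 summary metrics → thermogram PCA →
status linear models (23 parameters, FDR, Tukey contrasts) → NED-vs-active
logistic classification (VIF screen, stepwise selection, 25×5 stratified
CV) → overall-survival Cox/KM/RMST and NED progression-free survival.  All
stage outputs are tidy CSV/JSON files plus diagnostic figures, listed in a
manifest; every stochastic step derives from the single configured seed.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, metrics, pca, plots, status, survival
from .io import read_clinical_table, read_thermogram_matrix, linear_baseline_correct

__all__ = ["PipelineConfig", "run_pipeline", "build_cohort_table"]

log = logging.getLogger("thermoparam")


@dataclass
class PipelineConfig:
    """All pipeline settings (YAML-serializable)."""

    thermograms: str = ""
    clinical: str = ""
    out_dir: str = "thermoparam_report"
    seed: int = 0
    baseline_correct: bool = False
    baseline_pre_window: tuple[float, float] = (45.0, 50.0)
    baseline_post_window: tuple[float, float] = (85.0, 90.0)
    n_pcs: int = 5
    partial_f_alpha: float = 0.05
    vif_threshold: float = 5.0
    cv_repeats: int = 25
    cv_folds: int = 5
    rmst_tau: float = 8.0
    fdr_alpha: float = 0.05
    models: tuple[int, ...] = (1, 2, 3, 4)
    stepwise: bool = True

    def __post_init__(self) -> None:
        for name in ("vif_threshold", "cv_repeats", "cv_folds", "rmst_tau", "fdr_alpha",
                     "partial_f_alpha", "n_pcs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def build_cohort_table(curves, clinical: pd.DataFrame, n_pcs: int = 5) -> pd.DataFrame:
    """Join summary metrics, PC scores and clinical data on sample_id."""
    mtab = metrics.metrics_table(curves)
    decomp = pca.fit_pca(curves, k=n_pcs)
    table = mtab.join(decomp.scores)
    table = table.join(clinical.set_index("sample_id"))
    if table["status"].isna().any():
        missing = table.index[table["status"].isna()].tolist()
        raise ValueError(f"samples without clinical records: {missing}")
    return table


#: the 23 statistical parameters: 19 summary metrics + first four PCs
def statistical_parameters(table: pd.DataFrame) -> list[str]:
    return metrics.STATISTICAL_METRICS + [c for c in ("PC1", "PC2", "PC3", "PC4") if c in table.columns]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the manifest."""
    t0 = _time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    manifest: dict[str, str] = {}

    def emit(name: str, path: Path) -> None:
        manifest[name] = str(path)

    # ---- stage: input & preprocessing -------------------------------------
    log.info("reading thermograms from %s", config.thermograms)
    try:
        curves = read_thermogram_matrix(config.thermograms)
        clinical = read_clinical_table(config.clinical)
    except Exception as exc:
        raise RuntimeError(f"stage=input: {exc}") from exc
    if config.baseline_correct:
        curves = [
            linear_baseline_correct(c, config.baseline_pre_window, config.baseline_post_window)
            for c in curves
        ]

    # ---- stage: metrics + PCA ---------------------------------------------
    log.info("computing summary metrics and PCs for %d samples", len(curves))
    try:
        table = build_cohort_table(curves, clinical, n_pcs=config.n_pcs)
        decomp = pca.fit_pca(curves, k=config.n_pcs)
    except Exception as exc:
        raise RuntimeError(f"stage=metrics/pca: {exc}") from exc
    table_path = out / "cohort_table.csv"
    table.to_csv(table_path, float_format="%.8g")
    emit("cohort_table", table_path)
    decomp.save(out)
    emit("pca_loadings", out / "pca_loadings.csv")
    emit("pca_scores", out / "pca_scores.csv")
    emit("pca_meta", out / "pca_meta.json")
    emit("scree_plot", plots.scree_plot(decomp.explained_fraction, out / "scree.png"))
    params = statistical_parameters(table)

    # ---- stage: status linear models --------------------------------------
    log.info("status linear models over %d parameters", len(params))
    try:
        status_summary, status_results = status.fit_status_models(
            table, params, levels=["control", "NED", "active"],
            alpha=config.partial_f_alpha, fdr_alpha=config.fdr_alpha,
        )
    except Exception as exc:
        raise RuntimeError(f"stage=status_models: {exc}") from exc
    p = out / "status_models.csv"
    status_summary.to_csv(p, index=False, float_format="%.6g")
    emit("status_models", p)
    contrast_rows = [
        {"parameter": r.parameter, "sex": c.sex or "averaged",
         "contrast": c.label, "estimate": c.estimate, "se": c.se, "p_tukey": c.p_tukey}
        for r in status_results for c in r.contrasts
    ]
    p = out / "status_contrasts.csv"
    pd.DataFrame(contrast_rows).to_csv(p, index=False, float_format="%.6g")
    emit("status_contrasts", p)
    plot_dir = out / "diagnostics"
    plot_dir.mkdir(exist_ok=True)
    for r in status_results:
        fit = getattr(r, "_fit", None)
        if fit is not None and hasattr(fit, "resid"):
            safe = r.parameter.replace("/", "_").replace(".", "_")
            plots.residual_plots(
                np.asarray(fit.resid), np.asarray(fit.fittedvalues),
                plot_dir / f"resid_{safe}.png", title=r.parameter,
            )
    emit("diagnostic_plots", plot_dir)

    # ---- stage: NED vs active classification -------------------------------
    log.info("NED-vs-active classification")
    try:
        mel, y = classify.prepare_classification_table(table)
        thermo_params = [c for c in params if c in mel.columns]
        retained = classify.vif_reduce(mel[thermo_params], config.vif_threshold)
        classifier_report: dict = {"vif_retained": retained}
        if config.stepwise:
            fwd = classify.stepwise_select(mel, y, candidates=["age"] + retained,
                                           direction="forward", criterion="AIC")
            bwd_bic = classify.stepwise_select(mel, y, candidates=["age"] + retained,
                                              direction="forward", criterion="BIC")
            classifier_report["forward_aic"] = fwd.predictors
            classifier_report["forward_bic"] = bwd_bic.predictors
        cv_results = {}
        for model_id in config.models:
            spec = classify.MODEL_SPECS[model_id]
            fitted = classify.NedActiveLogit(table, spec)
            model = fitted.fit()
            report = fitted.cross_validate(
                repeats=config.cv_repeats, folds=config.cv_folds, seed=config.seed
            )
            cv_results[model_id] = {
                "coefficients": model.summary().to_dict(orient="records"),
                **report.as_dict(),
            }
            emit(
                f"roc_model{model_id}",
                plots.roc_band_plot(report, out / f"roc_model{model_id}.png"),
            )
        classifier_report["cross_validation"] = cv_results
    except Exception as exc:
        raise RuntimeError(f"stage=classification: {exc}") from exc
    p = out / "classification.json"
    p.write_text(json.dumps(classifier_report, indent=2, default=str))
    emit("classification", p)
    pd.DataFrame(
        [
            {"model": mid, "predictors": "+".join(res["predictors"]),
             "mean_auc": res["mean_auc"], "accuracy": res["accuracy"],
             "sensitivity": res["sensitivity"], "specificity": res["specificity"],
             "balanced_accuracy": res["balanced_accuracy"]}
            for mid, res in cv_results.items()
        ]
    ).to_csv(out / "classification_cv.csv", index=False, float_format="%.6g")
    emit("classification_cv", out / "classification_cv.csv")

    # ---- stage: survival ----------------------------------------------------
    log.info("survival analysis")
    try:
        active = table[table["status"] == "active"]
        os_screen, os_results = survival.cox_screen(active, params)
        p = out / "cox_univariate_os.csv"
        os_screen.to_csv(p, index=False, float_format="%.6g")
        emit("cox_univariate_os", p)
        sex_male = (active["sex"] == "male").astype(float)
        multi_table = active[["PC3", "V1.2.Peak2", "os_time", "os_event"]].copy()
        multi_table["sex_male"] = sex_male
        retained_cox = survival.cox_backward_bic(
            multi_table, ["PC3", "sex_male", "V1.2.Peak2"]
        )
        pd.DataFrame([r.as_row() for r in retained_cox]).to_csv(
            out / "cox_multivariable_os.csv", index=False, float_format="%.6g"
        )
        emit("cox_multivariable_os", out / "cox_multivariable_os.csv")
        split = survival.km_median_split(active["PC3"], active["os_time"], active["os_event"])
        emit("km_plot", plots.km_plot(split, out / "km_pc3.png"))
        arm = np.where(active["PC3"] > split.median_value, "above", "at-or-below")
        rmst = survival.rmst_compare(
            arm, active["os_time"], active["os_event"], tau=config.rmst_tau,
            level_order=("above", "at-or-below"),
        )
        surv_json = {
            "km_median_split": {
                "median_PC3": split.median_value,
                "logrank_statistic": split.logrank_statistic,
                "logrank_p": split.logrank_p,
                "n": split.n,
            },
            "rmst": rmst.as_row(),
        }
        try:
            pfs_screen, _ = survival.pfs_analysis(table, params)
            pfs_screen.to_csv(out / "cox_univariate_pfs.csv", index=False, float_format="%.6g")
            emit("cox_univariate_pfs", out / "cox_univariate_pfs.csv")
        except ValueError as exc:
            surv_json["pfs_note"] = str(exc)
        p = out / "survival.json"
        p.write_text(json.dumps(surv_json, indent=2, default=str))
        emit("survival", p)
    except Exception as exc:
        raise RuntimeError(f"stage=survival: {exc}") from exc

    # ---- manifest & log ------------------------------------------------------
    import thermoparam

    run_log = {
        "package_version": getattr(thermoparam, "__version__", "unknown"),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config": asdict(config),
        "elapsed_s": round(_time.time() - t0, 2),
        "n_samples": len(curves),
        "manifest": {k: str(v) for k, v in manifest.items()},
    }
    (out / "manifest.json").write_text(json.dumps(run_log, indent=2, default=str))
    log.info("pipeline complete in %.1fs; %d artifacts", run_log["elapsed_s"], len(manifest))
    return run_log
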