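"""End-to-end orchestrated workflow.

simulate/load -> average replicates -> outlier screening -> (optional)
preprocessing comparison -> calibration (four configurations: raw 3-LV
PLSR, EMSC 4-LV PLSR, 7-wavelength MLR, 7-wavelength 3-LV PLS) ->
validation -> table-shaped report and paired error comparisons.

Every stage is a pure function of (inputs, config, seed); validation data
are only ever transformed with calibration-fitted state (EMSC reference,
centering vectors), so train/apply leakage is structurally impossible
through this interface.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics, models, outliers, preprocess, wavelengths
from .exceptions import NirmcError, SelectionError
from .gravimetric import summarize_duplicates
from .simulate import SimConfig, make_default_config, simulate_dataset
from .spectra import SpectraSet, average_replicates, read_spectra, subset_wavelengths

log = logging.getLogger("nirmc")


@dataclass
class WorkflowConfig:
    """Everything a run needs; a run is reproducible from this + seed."""

    sim: SimConfig | None = field(default_factory=make_default_config)
    spectra_path: str | None = None      # load instead of simulate
    seed: int = 1
    raw_n_lv: int = 3
    emsc_n_lv: int = 4
    subset_n_lv: int = 3
    emsc_poly_order: int = 2
    n_wavelengths: int = 7
    min_separation: float = 20.0
    max_lv: int = 10
    outlier_alpha: float = 0.05
    outlier_n_pc: int = 2
    run_preprocessing_comparison: bool = False
    preprocessing_max_lv: int = 8
    #: None sweeps the full catalogue; a list of factories restricts it
    preprocessing_factories: list | None = None
    out_dir: str | None = None


@dataclass
class WorkflowResult:
    """Artifact bundle of one run."""

    outlier_table: pd.DataFrame
    outlier_decision: outliers.KeepDropDecision
    preprocessing_comparison: pd.DataFrame | None
    selected_wavelengths: np.ndarray
    reports: dict[str, metrics.ValidationReport]
    table: pd.DataFrame
    pvalues: dict[str, float]
    log_records: dict


MODEL_NAMES = ("raw_plsr", "emsc_plsr", "subset_mlr", "subset_pls")


def _model_reports(cal: SpectraSet, val: SpectraSet, y_cal, y_val,
                   cfg: WorkflowConfig):
    """Fit the four study configurations; return reports and residuals."""
    reports: dict[str, metrics.ValidationReport] = {}
    residuals: dict[str, np.ndarray] = {}

    def finish(name, y_hat_cal, y_hat_val, n_lv, rmsecv, r2_cv):
        rep = metrics.evaluate_predictions(y_val, y_hat_val, n_lv=n_lv)
        rep.r2_cal = models.r_squared(y_cal, y_hat_cal)
        rep.rmsec = models.rmse(y_cal, y_hat_cal)
        rep.rmsecv = rmsecv
        rep.r2_cv = r2_cv
        reports[name] = rep
        residuals[name] = np.asarray(y_hat_val) - np.asarray(y_val)

    # 1. raw full-spectrum PLSR
    raw = models.fit_plsr(cal.X, y_cal, cfg.raw_n_lv)
    curve = models.full_cross_validation(cal.X, y_cal, cfg.raw_n_lv)
    finish("raw_plsr", raw.fitted, raw.predict(val.X), cfg.raw_n_lv,
           float(curve.rmsecv[-1]), float(curve.r2_cv[-1]))

    # 2. EMSC-corrected PLSR (EMSC fitted on calibration only)
    emsc = preprocess.fit_scatter(cal, "emsc", cfg.emsc_poly_order)
    Zc, Zv = emsc.transform(cal.X), emsc.transform(val.X)
    emsc_pls = models.fit_plsr(Zc, y_cal, cfg.emsc_n_lv)
    curve = models.full_cross_validation(Zc, y_cal, cfg.emsc_n_lv)
    finish("emsc_plsr", emsc_pls.fitted, emsc_pls.predict(Zv), cfg.emsc_n_lv,
           float(curve.rmsecv[-1]), float(curve.r2_cv[-1]))

    # 3. wavelength selection from the raw PLSR coefficients
    try:
        selected = wavelengths.select_wavelengths(
            raw.b, cal.grid, k=cfg.n_wavelengths,
            min_separation=cfg.min_separation)
    except SelectionError:
        # degenerate coefficient structure: fall back to the published set
        selected = np.array(wavelengths.PUBLISHED_WAVELENGTHS)
        log.warning("peak selection found too few peaks; using the "
                    "published wavelength set")
    cal_sub = subset_wavelengths(cal, selected, tolerance=cal.grid.values[1]
                                 - cal.grid.values[0] + 2.0)
    val_sub = subset_wavelengths(val, selected, tolerance=cal.grid.values[1]
                                 - cal.grid.values[0] + 2.0)

    mlr = models.fit_mlr(cal_sub.X, y_cal, wavelengths=cal_sub.grid.values)
    lev_rmse = models.leverage_corrected_rmse(mlr, cal_sub.X, y_cal)
    sst = float(np.sum((y_cal - np.mean(y_cal)) ** 2))
    r2_lev = 1.0 - lev_rmse ** 2 * len(y_cal) / sst
    finish("subset_mlr", mlr.fitted, mlr.predict(val_sub.X), None,
           lev_rmse, r2_lev)

    pls_sub = models.fit_plsr(cal_sub.X, y_cal, cfg.subset_n_lv,
                              wavelengths=cal_sub.grid.values)
    curve = models.full_cross_validation(cal_sub.X, y_cal, cfg.subset_n_lv)
    finish("subset_pls", pls_sub.fitted, pls_sub.predict(val_sub.X),
           cfg.subset_n_lv, float(curve.rmsecv[-1]), float(curve.r2_cv[-1]))

    return reports, residuals, selected


def run_workflow(cfg: WorkflowConfig) -> WorkflowResult:
    """Run the full pipeline deterministically; optionally write artifacts."""
    if cfg.spectra_path is not None:
        replicate_set = read_spectra(cfg.spectra_path)
        if replicate_set.reference_mc is None:
            raise NirmcError("loaded spectra carry no reference MC values")
        log.info("loaded %d spectra from %s", len(replicate_set),
                 cfg.spectra_path)
    else:
        sim = cfg.sim or make_default_config()
        replicate_set, records, _ = simulate_dataset(sim, cfg.seed)
        # reference MC from the duplicate gravimetric records
        summary = summarize_duplicates(records)
        mc_map = dict(zip(summary.per_sample["sample_id"],
                          summary.per_sample["mc_percent"]))
        replicate_set.reference_mc = np.array(
            [mc_map[s] for s in replicate_set.meta["sample_id"]])
        log.info("simulated %d replicate spectra (seed %d)",
                 len(replicate_set), cfg.seed)

    averaged = average_replicates(replicate_set)
    role = averaged.meta["role"].to_numpy()
    cal = averaged.take(np.flatnonzero(role == "calibration"))
    val = averaged.take(np.flatnonzero(role == "validation"))
    y_cal, y_val = cal.reference_mc, val.reference_mc
    log.info("averaged to %d samples: %d calibration / %d validation",
             len(averaged), len(cal), len(val))

    # outlier screening on all samples' raw spectra
    pca = outliers.fit_pca(averaged, cfg.outlier_n_pc)
    flags = outliers.flag_outliers(pca, cfg.outlier_alpha)
    flagged_cal = [s for s in flags.loc[flags.flagged, "sample_id"]
                   if s in set(cal.meta["sample_id"])]
    decision = outliers.keep_or_drop(cal, y_cal, flagged_cal,
                                     n_lv=cfg.raw_n_lv)
    log.info("outlier screening: %d flagged, recommendation %s",
             int(flags["flagged"].sum()), decision.recommendation)

    comparison = None
    if cfg.run_preprocessing_comparison:
        comparison = preprocess.compare_preprocessing(
            cal, y_cal, max_lv=cfg.preprocessing_max_lv,
            factories=cfg.preprocessing_factories)
        log.info("preprocessing comparison: best %s (RMSECV %.3f)",
                 comparison.iloc[0]["name"], comparison.iloc[0]["rmsecv"])

    reports, residuals, selected = _model_reports(cal, val, y_cal, y_val, cfg)
    table = metrics.report_table([(n, reports[n]) for n in MODEL_NAMES])

    pvalues = {
        "subset_pls_vs_subset_mlr": metrics.compare_prediction_errors(
            residuals["subset_pls"], residuals["subset_mlr"]),
        "subset_pls_vs_raw_plsr": metrics.compare_prediction_errors(
            residuals["subset_pls"], residuals["raw_plsr"]),
        "emsc_plsr_vs_raw_plsr": metrics.compare_prediction_errors(
            residuals["emsc_plsr"], residuals["raw_plsr"]),
    }

    log_records = {
        "seed": cfg.seed,
        "n_cal": len(cal), "n_val": len(val),
        "selected_wavelengths": [float(w) for w in selected],
        "model_n_lv": {"raw_plsr": cfg.raw_n_lv, "emsc_plsr": cfg.emsc_n_lv,
                       "subset_mlr": None, "subset_pls": cfg.subset_n_lv},
        "outlier": {"flagged": decision.flagged,
                    "recommendation": decision.recommendation,
                    "rmsecv_with": decision.rmsecv_with,
                    "rmsecv_without": decision.rmsecv_without},
        "pvalues": pvalues,
    }
    result = WorkflowResult(flags, decision, comparison, selected, reports,
                            table, pvalues, log_records)
    if cfg.out_dir:
        _write_artifacts(result, Path(cfg.out_dir))
    return result


def _write_artifacts(result: WorkflowResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    outliers.outlier_report(result.outlier_table, result.outlier_decision) \
        .to_csv(out_dir / "outliers.csv", index=False)
    if result.preprocessing_comparison is not None:
        result.preprocessing_comparison.to_csv(
            out_dir / "preprocessing_comparison.csv", index=False)
    result.table.to_csv(out_dir / "model_table.csv")
    (out_dir / "model_table.txt").write_text(
        metrics.report_text(result.table) + "\n", encoding="utf-8")
    (out_dir / "run_log.json").write_text(
        json.dumps(result.log_records, indent=2, sort_keys=True) + "\n",
        encoding="utf-8")
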