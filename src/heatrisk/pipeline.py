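"""End-to-end orchestration: ingest → HI → features → models → scenarios.

``run_pipeline`` sequences the stages with per-stage logging of record
counts and seeds, and emits a single JSON report plus CSV artifacts.  Any
stage failure aborts the run with the stage name attached.  Reruns with the
same configuration are byte-identical up to the report's wall-clock-free
content (no timestamps are recorded).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, ingest, modeling, scenarios, synthetic
from .config import PipelineConfig
from .heat_index import apply_heat_index
from .modeling import ModelSpec, derive_seed

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("heatrisk")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
                raise PipelineError(name, exc) from exc
            return out
        return inner
    return wrap


@_stage("ingest")
def _load_series(config: PipelineConfig) -> pd.DataFrame:
    if config.use_dhaka_preset:
        gen = synthetic.dhaka_like_config(
            seed=derive_seed(config.master_seed, "synthetic")
        )
        series = synthetic.generate_climate(gen)
        log.info("ingest: generated %d synthetic records (Dhaka-like preset)", len(series))
    elif config.synthetic is not None:
        gen = config.synthetic_config(derive_seed(config.master_seed, "synthetic"))
        series = synthetic.generate_climate(gen)
        log.info("ingest: generated %d synthetic records", len(series))
    else:
        if config.temp_path is None or config.rh_path is None:
            raise FileNotFoundError("temp_path and rh_path are both required")
        temp_long, rh_long = ingest.read_wide_tables(config.temp_path, config.rh_path)
        series = ingest.merge_long(temp_long, rh_long)
        log.info("ingest: merged %d records from wide tables", len(series))
    return series


@_stage("qc")
def _qc(series: pd.DataFrame) -> ingest.QCReport:
    calendar = modeling.encode_calendar(series.index)
    vif_features = pd.concat(
        [series[["temperature_c", "relative_humidity_pct"]],
         calendar[["hour", "month"]]],
        axis=1,
    )
    report = ingest.qc_report(series, vif_features)
    if report.n_missing_timestamps > 0:
        raise ValueError(
            f"{report.n_missing_timestamps} missing timestamps; "
            "the pipeline requires a complete 3-hourly grid"
        )
    log.info(
        "qc: %d records, %d outlier flags (retained), max VIF %.2f",
        report.n_records, len(report.outlier_flags), max(report.vif.values()),
    )
    return report


def _fit_models(config: PipelineConfig, train, test):
    results = {}
    fitted = {}
    for name in config.models:
        spec = ModelSpec(
            name=name,
            hyperparameters=dict(config.hyperparameters.get(name, {})),
            seed=derive_seed(config.master_seed, f"model:{name}"),
        )
        try:
            model = modeling.fit(spec, train)
            yhat = model.predict(test)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"fit:{name}", exc) from exc
        metrics = evaluation.compute_metrics(test["hi"].to_numpy(), yhat)
        entry = {"seed": spec.seed, "metrics": metrics.to_dict()}
        resid = test["hi"].to_numpy() - yhat
        entry["diagnostics"] = {
            "durbin_watson": evaluation.durbin_watson(resid),
            "breusch_pagan_p": evaluation.breusch_pagan(resid, yhat)[1],
        }
        if name in config.cv_models:
            entry["cv"] = modeling.expanding_window_cv(spec, train, config.cv_folds)
        fitted[name] = model
        results[name] = entry
        log.info("fit: %s test RMSE %.3f MASE %.3f",
                 name, metrics.rmse, metrics.mase)
    return fitted, results


@_stage("project")
def _project(config: PipelineConfig, model, series_hi, train):
    clim = scenarios.monthly_climatology(series_hi)
    grid = scenarios.build_future_grid(config.horizon_start, config.horizon_end)
    init_hi = series_hi["hi_c"].to_numpy()[-6:]
    out = {}
    frames = []
    for name in config.scenarios:
        spec = scenarios.ScenarioSpec.preset(
            name, seed=derive_seed(config.master_seed, f"scenario:{name}")
        )
        future_climate = scenarios.apply_scenario(clim, grid, spec)
        future = pd.concat([future_climate, grid], axis=1)
        proj = scenarios.recursive_project(model, future, init_hi, name)
        frames.append(proj)
        out[name] = {
            "seed": spec.seed,
            "mean_hi_c": float(proj["point"].mean()),
            "n": len(proj),
            "category_shares_pct": evaluation.category_distribution(
                proj["category"]
            ).to_dict(),
        }
        log.info("project: %s mean HI %.2f °C over %d steps",
                 name, out[name]["mean_hi_c"], len(proj))
    return out, pd.concat(frames)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the report dict and writes
    ``report.json``, ``hi_series.csv`` and ``projections.csv`` to the
    configured output directory."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    series = _load_series(config)
    qc = _qc(series)
    series_hi = apply_heat_index(series, config.steadman_mode)

    try:
        features = modeling.build_features(series_hi)
        train, test = modeling.chronological_split(features, config.split_boundary)
        log.info("features: %d rows -> train %d / test %d",
                 len(features), len(train), len(test))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("features", exc) from exc

    fitted, model_results = _fit_models(config, train, test)

    report: dict = {
        "config": json.loads(config.to_json()),
        "master_seed": config.master_seed,
        "qc": {
            "n_records": qc.n_records,
            "n_missing_timestamps": qc.n_missing_timestamps,
            "n_outlier_flags": len(qc.outlier_flags),
            "vif": qc.vif,
        },
        "historical_category_shares_pct": evaluation.category_distribution(
            series_hi["category"]
        ).to_dict(),
        "models": model_results,
    }

    proj_model = fitted.get(config.projection_model)
    if proj_model is not None and config.scenarios:
        if isinstance(proj_model, modeling.ForestAdapter):
            tree_preds = proj_model.tree_predictions(test)
            _, lower, upper = scenarios.empirical_interval(tree_preds)
            coverage, width = scenarios.interval_calibration(
                lower, upper, test["hi"].to_numpy()
            )
            report["interval_calibration"] = {
                "coverage_pct": coverage,
                "mean_width_c": width,
                "n": len(test),
            }
            log.info("calibration: coverage %.2f%%, width %.2f °C", coverage, width)
        scenario_report, projections = _project(config, proj_model, series_hi, train)
        report["scenarios"] = scenario_report
        projections.to_csv(out_dir / "projections.csv")

    series_hi.to_csv(out_dir / "hi_series.csv")
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    log.info("report written to %s", out_dir / "report.json")
    return report
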