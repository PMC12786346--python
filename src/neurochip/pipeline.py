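"""End-to-end orchestration: mechanics sweep -> synthetic (or supplied)
measurements -> calibration -> quantification -> stratified report.

Every stage is a pure function of ``(RunConfig, seed)``; re-running the
same configuration rewrites byte-identical artifacts.  Units are fixed
at the I/O boundary and embedded in column names (``sigma_hat_kPa``,
``conc_pg_ml``, ``I0_uA``, ...) to prevent silent unit drift.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import biosensing as bs
from . import injury_response as ir
from . import mechanics as mech
from . import synthetic_data as sd

__all__ = ["RunConfig", "load_run_config", "run_pipeline"]

log = logging.getLogger("neurochip")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    geometry: mech.TubeGeometry = mech.TubeGeometry()
    material: mech.OgdenMaterial = mech.OgdenMaterial()
    loading_matrix_csv: Optional[str] = None  # None -> default 25 conditions
    generator: sd.GeneratorConfig = sd.GeneratorConfig()
    calibration_source: str = "fit"  # "fit" | "reference"
    evaluation_radius_mm: Optional[float] = None  # None -> inner wall
    severity_threshold_kPa: float = mech.SEVERITY_THRESHOLD_KPA
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.calibration_source not in ("fit", "reference"):
            raise ValueError(
                f"calibration_source must be 'fit' or 'reference', "
                f"got {self.calibration_source!r}"
            )
        if self.loading_matrix_csv is not None and not Path(self.loading_matrix_csv).exists():
            raise FileNotFoundError(
                f"loading matrix CSV not found: {self.loading_matrix_csv}"
            )
        # one seed drives everything
        object.__setattr__(
            self, "generator", sd.GeneratorConfig(
                **{**_dataclass_dict(self.generator), "seed": self.seed}
            )
        )

    def to_dict(self) -> dict:
        return {
            "geometry": _dataclass_dict(self.geometry),
            "material": _dataclass_dict(self.material),
            "loading_matrix_csv": self.loading_matrix_csv,
            "generator": _dataclass_dict(self.generator),
            "calibration_source": self.calibration_source,
            "evaluation_radius_mm": self.evaluation_radius_mm,
            "severity_threshold_kPa": self.severity_threshold_kPa,
            "seed": self.seed,
            "log_level": self.log_level,
        }


def _dataclass_dict(obj) -> dict:
    # tuples become lists so the dict round-trips through JSON unchanged
    return {
        k: list(v) if isinstance(v := getattr(obj, k), tuple) else v
        for k in obj.__dataclass_fields__
    }


def load_run_config(path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file.

    Schema (all keys optional)::

        geometry: {L_mm, R_int_mm, R_ext_mm}
        material: {mu_kPa, alpha, D_per_kPa}
        loading_matrix_csv: path
        generator: {noise_dpv_uA, n_cal_replicates, n_cells,
                    n_bio_replicates, timecourse_cv, ct_sd}
        calibration_source: fit | reference
        evaluation_radius_mm: float
        severity_threshold_kPa: float
        seed: int
        log_level: str
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    geo = raw.get("geometry", {})
    mat = raw.get("material", {})
    gen = dict(raw.get("generator", {}))
    gen.setdefault("seed", raw.get("seed", 0))
    return RunConfig(
        geometry=mech.TubeGeometry(
            L=geo.get("L_mm", 50.0),
            R_int=geo.get("R_int_mm", 0.75),
            R_ext=geo.get("R_ext_mm", 2.5),
        ),
        material=mech.OgdenMaterial(
            mu=mat.get("mu_kPa", 19.14),
            alpha=mat.get("alpha", 1.5),
            D=mat.get("D_per_kPa", 3e-8),
        ),
        loading_matrix_csv=raw.get("loading_matrix_csv"),
        generator=sd.GeneratorConfig(**gen),
        calibration_source=raw.get("calibration_source", "fit"),
        evaluation_radius_mm=raw.get("evaluation_radius_mm"),
        severity_threshold_kPa=raw.get(
            "severity_threshold_kPa", mech.SEVERITY_THRESHOLD_KPA
        ),
        seed=raw.get("seed", 0),
        log_level=raw.get("log_level", "INFO"),
    )


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _conditions(config: RunConfig) -> list[mech.LoadingCondition]:
    if config.loading_matrix_csv is not None:
        return mech.read_loading_matrix(config.loading_matrix_csv)
    return mech.default_loading_matrix()


def stage_sweep(config: RunConfig) -> pd.DataFrame:
    return mech.sweep_loading_matrix(
        _conditions(config),
        geometry=config.geometry,
        material=config.material,
        evaluation_radius=config.evaluation_radius_mm,
        severity_threshold_kPa=config.severity_threshold_kPa,
    )


def stage_calibration(config: RunConfig) -> tuple[pd.DataFrame, list[bs.CalibrationModel]]:
    points = []
    models = []
    for analyte in bs.ANALYTES:
        for matrix in bs.MATRICES:
            series = sd.gen_calibration_series(analyte, matrix, config.generator)
            points.extend(series)
            if config.calibration_source == "fit":
                models.append(bs.fit_calibration(series))
            else:
                models.append(bs.reference_model(analyte, matrix))
    return bs.calibration_frame(points), models


def stage_measurements(
    config: RunConfig, conditions: list[mech.LoadingCondition]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Synthetic study: DPV time-course readings, qPCR table, apoptosis table."""
    readings = pd.concat(
        [
            sd.gen_dpv_timecourse(cond, analyte, config.generator)
            for cond in conditions
            for analyte in bs.ANALYTES
        ],
        ignore_index=True,
    )
    qpcr_rows = []
    for cond in conditions:
        for gene in ir.GENES:
            cts = sd.gen_qpcr(cond, gene, config.generator)
            res = ir.ddct_fold_change(*cts, gene=gene, condition=cond.label)
            qpcr_rows.append(
                {
                    "condition_id": cond.label,
                    "gene": gene,
                    "ct_target_load": cts[0],
                    "ct_ref_load": cts[1],
                    "ct_target_static": cts[2],
                    "ct_ref_static": cts[3],
                    "delta_delta_ct": res.delta_delta_ct,
                    "fold_change": res.fold_change,
                }
            )
    apo_rows = []
    for cond in conditions:
        res = sd.gen_apoptosis_counts(cond, config.generator)
        apo_rows.append(
            {
                "condition_id": cond.label,
                "n_cells": res.n_cells,
                "n_positive": res.n_positive,
                "fraction": res.fraction,
            }
        )
    return readings, pd.DataFrame(qpcr_rows), pd.DataFrame(apo_rows)


def stage_quantify(
    readings: pd.DataFrame, models: list[bs.CalibrationModel], matrix: str = "DMEM"
) -> pd.DataFrame:
    """Invert DPV current pairs to concentrations (pg/mL)."""
    by_analyte = {m.analyte: m for m in models if m.matrix == matrix}
    missing = set(readings["analyte"]) - set(by_analyte)
    if missing:
        raise ValueError(f"no {matrix} calibration model for analytes {sorted(missing)}")
    out = readings.copy()
    conc = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", bs.ExtrapolationWarning)
        for row in readings.itertuples():
            c_fg = bs.invert_concentration(by_analyte[row.analyte], row.I0_uA, row.Ic_uA)
            conc.append(c_fg / 1e3)
    out["conc_pg_ml"] = conc
    return out[["condition_id", "analyte", "time_min", "replicate", "conc_pg_ml"]]


def stage_report(
    sweep: pd.DataFrame,
    quantified: pd.DataFrame,
    apoptosis: pd.DataFrame,
    peak_time_min: float = 15.0,
) -> pd.DataFrame:
    """Stratified per-condition report from quantified measurements."""
    peaks = (
        quantified[quantified["time_min"] == peak_time_min]
        .groupby(["condition_id", "analyte"], as_index=False)["conc_pg_ml"]
        .mean()
    )
    return ir.stratify_conditions(sweep, peaks, apoptosis)


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage and write the report bundle to ``outdir``.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    stages = {}

    def timed(name, fn, *args):
        t0 = time.perf_counter()
        try:
            result = fn(*args)
        except Exception:
            log.error("pipeline stage %r failed", name)
            raise
        stages[name] = round(time.perf_counter() - t0, 4)
        log.info("stage %s done in %.3f s", name, stages[name])
        return result

    conditions = _conditions(config)
    sweep = timed("sweep", stage_sweep, config)
    cal_points, models = timed("calibration", stage_calibration, config)
    readings, qpcr, apoptosis = timed("measurements", stage_measurements, config, conditions)
    quantified = timed("quantify", stage_quantify, readings, models)
    report = timed("report", stage_report, sweep, quantified, apoptosis)

    _write_csv(sweep, outdir / "sweep.csv")
    _write_csv(cal_points, outdir / "calibration_data.csv")
    bs.write_models_json(models, outdir / "calibration_models.json")
    _write_csv(readings, outdir / "timecourse_readings.csv")
    _write_csv(quantified, outdir / "timecourse_quantified.csv")
    _write_csv(qpcr, outdir / "qpcr.csv")
    _write_csv(apoptosis, outdir / "apoptosis.csv")
    _write_csv(report, outdir / "report.csv")
    heatmap = report.set_index("condition_id")[
        ["TTau_fold", "NFL_fold", "sigma_hat_kPa", "apoptosis_frac"]
    ]
    heatmap.to_csv(outdir / "heatmap.csv", float_format="%.10g")

    config_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "package": "neurochip",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "n_conditions": len(conditions),
        "outputs": sorted(
            p.name for p in outdir.iterdir() if p.name != "manifest.json"
        ),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
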