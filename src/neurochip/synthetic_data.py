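"""Seeded generators for every measurement the analysis pipeline consumes.

The generators stand in for the wet-lab instrument outputs and reproduce
their statistical structure:

* DPV calibration series — current drops on the published log-linear
  lines with additive Gaussian noise (sigma 0.5 uA) and a jittered
  BSA-blocked baseline; 8 decade-spaced levels (100 fg/mL to 1 ug/mL)
  in triplicate per analyte/matrix pair.
* Biomarker time courses — the mean release curve sampled on the
  {15, 30, 60, 90, 120} min grid with multiplicative log-normal noise
  (CV 0.15), five replicates per condition.
* qPCR Ct quadruples — constructed so the expected fold change equals
  the packaged response table, with Gaussian noise (sigma 0.15 cycles)
  per Ct value.
* Caspase-3 counts — binomial draws (default 500 cells per field) at
  the tabulated per-condition apoptosis probability.

Noise families follow the standard model for each measurement class:
additive Gaussian for currents and Ct values, multiplicative log-normal
for concentrations, binomial for cell counts.

Reproducibility: every generator derives an independent child stream
from ``(config.seed, generator name, condition/analyte/... key)`` via a
CRC32 hash, so a fixed seed gives byte-identical output and adding one
generator call never perturbs the draws of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import injury_response as ir
from .biosensing import (
    BASELINE_I0_UA,
    REFERENCE_LINES,
    CalibrationPoint,
)
from .mechanics import LoadingCondition

__all__ = [
    "GeneratorConfig",
    "gen_calibration_series",
    "gen_timecourse",
    "gen_qpcr",
    "gen_apoptosis_counts",
    "gen_dpv_timecourse",
    "timecourse_frame",
]

#: Default calibration levels: 8 decade-spaced concentrations,
#: 100 fg/mL to 1 ug/mL (= 1e9 fg/mL).
_DEFAULT_CAL_LEVELS = tuple(10.0**k for k in range(2, 10))

#: Gaussian jitter on the blank baseline current, uA.
_I0_JITTER_UA = 0.3


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study; defaults match the study design."""

    seed: int = 0
    noise_dpv_uA: float = 0.5
    n_cal_replicates: int = 3
    cal_levels: tuple = _DEFAULT_CAL_LEVELS
    n_cells: int = 500
    n_bio_replicates: int = 5
    timecourse_cv: float = 0.15
    ct_sd: float = 0.15

    def __post_init__(self) -> None:
        if min(self.noise_dpv_uA, self.timecourse_cv, self.ct_sd) < 0:
            raise ValueError("noise scales must be nonnegative")
        if not self.cal_levels:
            raise ValueError("calibration level grid must be non-empty")
        object.__setattr__(self, "cal_levels", tuple(self.cal_levels))
        if min(self.n_cal_replicates, self.n_bio_replicates, self.n_cells) < 1:
            raise ValueError("replicate/cell counts must be positive")


def _rng(config: GeneratorConfig, *key_parts) -> np.random.Generator:
    """Independent child stream keyed on the generator identity."""
    tag = zlib.crc32("|".join(str(p) for p in key_parts).encode())
    return np.random.default_rng(np.random.SeedSequence([config.seed, tag]))


# ---------------------------------------------------------------------------
# DPV calibration series
# ---------------------------------------------------------------------------

def gen_calibration_series(
    analyte: str,
    matrix: str,
    config: GeneratorConfig = GeneratorConfig(),
) -> list[CalibrationPoint]:
    """Synthetic dilution-series DPV measurements for one sensor.

    The current drop is drawn as ``a*log10(c) + b + N(0, noise_dpv_uA)``
    on the published line for the pair, and the response current is
    derived from a jittered blank baseline.
    """
    if (analyte, matrix) not in REFERENCE_LINES:
        raise KeyError(
            f"no ground-truth line for ({analyte}, {matrix}); known pairs: "
            f"{sorted(REFERENCE_LINES)}"
        )
    a, b = REFERENCE_LINES[(analyte, matrix)]
    baseline = BASELINE_I0_UA[analyte]
    rng = _rng(config, "calibration", analyte, matrix)
    points: list[CalibrationPoint] = []
    for conc in config.cal_levels:
        for _ in range(config.n_cal_replicates):
            signal = a * np.log10(conc) + b + rng.normal(0.0, config.noise_dpv_uA)
            I0 = baseline + rng.normal(0.0, _I0_JITTER_UA)
            points.append(
                CalibrationPoint(
                    analyte=analyte,
                    matrix=matrix,
                    concentration=float(conc),
                    I0=float(I0),
                    Ic=float(I0 - signal),
                )
            )
    return points


# ---------------------------------------------------------------------------
# Biomarker time courses
# ---------------------------------------------------------------------------

def _lognormal_factors(
    rng: np.random.Generator, cv: float, size
) -> np.ndarray:
    """Multiplicative noise with unit mean and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def gen_timecourse(
    condition: LoadingCondition,
    analyte: str,
    config: GeneratorConfig = GeneratorConfig(),
    timepoints: Sequence[float] = ir.TIME_GRID_MIN,
) -> list[ir.BiomarkerTimeSeries]:
    """Replicate biomarker time courses for one condition and analyte."""
    model = ir.default_kinetics(analyte)
    mean = np.asarray(
        [ir.mean_concentration(model, condition, float(t)) for t in timepoints]
    )
    rng = _rng(config, "timecourse", analyte, condition.label)
    series = []
    for rep in range(config.n_bio_replicates):
        factors = _lognormal_factors(rng, config.timecourse_cv, mean.shape)
        series.append(
            ir.BiomarkerTimeSeries(
                condition=condition.label,
                analyte=analyte,
                timepoints=tuple(timepoints),
                concentrations=tuple(mean * factors),
                replicate=rep,
            )
        )
    return series


def timecourse_frame(series: Sequence[ir.BiomarkerTimeSeries]) -> pd.DataFrame:
    """Time courses as the canonical long CSV schema."""
    rows = []
    for s in series:
        for t, c in zip(s.timepoints, s.concentrations):
            rows.append(
                {
                    "condition_id": s.condition,
                    "analyte": s.analyte,
                    "time_min": t,
                    "replicate": s.replicate,
                    "conc_pg_ml": c,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

#: Noise-free anchor Ct values for the reference gene (Gapdh) and the
#: target genes in the static control; arbitrary within the usual 10-40
#: cycle range, they cancel in the ddCt difference.
_CT_REF = 20.0
_CT_TARGET_STATIC = 24.0


def gen_qpcr(
    condition: LoadingCondition,
    gene: str,
    config: GeneratorConfig = GeneratorConfig(),
) -> tuple[float, float, float, float]:
    """Synthetic Ct quadruple ``(target_load, ref_load, target_static, ref_static)``.

    Constructed so that the noise-free ddCt fold change equals the
    packaged fold-change table entry for (gene, condition); Gaussian
    noise of ``ct_sd`` cycles is added per Ct value.
    """
    if gene not in ir.FOLD_CHANGE_TABLE:
        raise KeyError(f"unknown gene {gene!r}; known: {sorted(ir.FOLD_CHANGE_TABLE)}")
    fold = ir.FOLD_CHANGE_TABLE[gene][condition.key]
    rng = _rng(config, "qpcr", gene, condition.label)
    noise = rng.normal(0.0, config.ct_sd, size=4)
    ct_target_load = _CT_TARGET_STATIC - np.log2(fold) + noise[0]
    ct_ref_load = _CT_REF + noise[1]
    ct_target_static = _CT_TARGET_STATIC + noise[2]
    ct_ref_static = _CT_REF + noise[3]
    return (
        float(ct_target_load),
        float(ct_ref_load),
        float(ct_target_static),
        float(ct_ref_static),
    )


# ---------------------------------------------------------------------------
# Apoptosis counts
# ---------------------------------------------------------------------------

def gen_apoptosis_counts(
    condition: LoadingCondition,
    config: GeneratorConfig = GeneratorConfig(),
) -> ir.ApoptosisResult:
    """Binomial Caspase-3-positive count for one imaging field."""
    try:
        p = ir.APOPTOSIS_TABLE[condition.key]
    except KeyError:
        raise KeyError(
            f"condition {condition.label!r} not in the apoptosis table"
        ) from None
    rng = _rng(config, "apoptosis", condition.label)
    n_positive = int(rng.binomial(config.n_cells, p))
    return ir.ApoptosisResult(
        condition=condition.label,
        n_cells=config.n_cells,
        n_positive=n_positive,
    )


# ---------------------------------------------------------------------------
# DPV readings of the time courses (sensor-facing output)
# ---------------------------------------------------------------------------

def gen_dpv_timecourse(
    condition: LoadingCondition,
    analyte: str,
    config: GeneratorConfig = GeneratorConfig(),
    matrix: str = "DMEM",
    timepoints: Sequence[float] = ir.TIME_GRID_MIN,
) -> pd.DataFrame:
    """Raw DPV current pairs for the biomarker time course of one sensor.

    The latent concentrations are the log-normal-noised time courses of
    :func:`gen_timecourse` (pg/mL, converted to fg/mL); the sensor reads
    them through the true response line of the analyte in ``matrix``
    with additive DPV noise.  Columns: condition_id, analyte, time_min,
    replicate, I0_uA, Ic_uA.
    """
    a, b = REFERENCE_LINES[(analyte, matrix)]
    baseline = BASELINE_I0_UA[analyte]
    series = gen_timecourse(condition, analyte, config, timepoints)
    rng = _rng(config, "dpv_timecourse", analyte, condition.label)
    rows = []
    for s in series:
        for t, conc_pg in zip(s.timepoints, s.concentrations):
            conc_fg = conc_pg * 1e3
            signal = a * np.log10(conc_fg) + b + rng.normal(0.0, config.noise_dpv_uA)
            I0 = baseline + rng.normal(0.0, _I0_JITTER_UA)
            rows.append(
                {
                    "condition_id": s.condition,
                    "analyte": analyte,
                    "time_min": t,
                    "replicate": s.replicate,
                    "I0_uA": float(I0),
                    "Ic_uA": float(I0 - signal),
                }
            )
    return pd.DataFrame(rows)
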