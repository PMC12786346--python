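"""Log-linear calibration and inversion of DPV immunosensor signals.

The electrochemical immunosensors report a differential-pulse-voltammetry
(DPV) peak current that decreases as antigen (total tau or neurofilament
light chain) binds the antibody-functionalised electrode.  The working
signal is the current drop relative to a BSA-blocked blank electrode,

    dI = I0 - Ic   (microamperes),

which is linear in the decadic log of concentration over roughly seven
orders of magnitude (0.1 pg/mL to 1 ug/mL):

    dI = a * log10(c [fg/mL]) + b.

The log base and concentration unit of the published fit equations are
fixed here as log10 of fg/mL: that choice keeps the signal positive over
the entire calibrated range (100 fg/mL -> X = 2) and predicts ~47 uA at
10 ng/mL, consistent with the measured ~43 uA drops.

Reference lines (slope a in uA/decade, intercept b in uA) for the four
analyte/matrix pairs, with their blank baselines I0:

    T-Tau / PBS   a = 7.84, b = -7.51     I0 = 72.2 uA
    NFL   / PBS   a = 8.01, b = -8.62     I0 = 75.7 uA
    T-Tau / DMEM  a = 7.92, b = -2.41
    NFL   / DMEM  a = 7.71, b = -1.23
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ANALYTES",
    "MATRICES",
    "REFERENCE_LINES",
    "BASELINE_I0_UA",
    "CalibrationPoint",
    "CalibrationModel",
    "ExtrapolationWarning",
    "fit_calibration",
    "predict_signal",
    "invert_concentration",
    "limit_of_detection",
    "reference_model",
    "read_calibration_csv",
    "write_models_json",
    "read_models_json",
]

ANALYTES = ("T-Tau", "NFL")
MATRICES = ("PBS", "DMEM")

#: (slope uA/decade, intercept uA) of dI vs log10(conc fg/mL).
REFERENCE_LINES: dict[tuple[str, str], tuple[float, float]] = {
    ("T-Tau", "PBS"): (7.84, -7.51),
    ("NFL", "PBS"): (8.01, -8.62),
    ("T-Tau", "DMEM"): (7.92, -2.41),
    ("NFL", "DMEM"): (7.71, -1.23),
}

#: DPV peak current of the BSA-blocked blank electrode, uA.
BASELINE_I0_UA: dict[str, float] = {"NFL": 75.7, "T-Tau": 72.2}


class ExtrapolationWarning(UserWarning):
    """Signal lies outside the calibrated range; the value is extrapolated."""


@dataclass(frozen=True)
class CalibrationPoint:
    """One DPV measurement of a known standard."""

    analyte: str
    matrix: str
    concentration: float  # fg/mL
    I0: float  # uA, blank baseline
    Ic: float  # uA, response current

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError(f"concentration must be positive, got {self.concentration}")
        if self.I0 <= 0:
            raise ValueError(f"baseline current must be positive, got {self.I0}")

    @property
    def signal(self) -> float:
        """Current drop dI = I0 - Ic in uA."""
        return self.I0 - self.Ic


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted log-linear response of one analyte/matrix pair."""

    analyte: str
    matrix: str
    slope: float  # uA per decade
    intercept: float  # uA
    r_squared: float
    x_units: str = "log10(fg/mL)"
    x_range: Optional[tuple[float, float]] = None  # calibrated log10 range

    def to_dict(self) -> dict:
        d = {
            "analyte": self.analyte,
            "matrix": self.matrix,
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.r_squared,
            "x_units": self.x_units,
        }
        if self.x_range is not None:
            d["x_range"] = list(self.x_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            analyte=d["analyte"],
            matrix=d["matrix"],
            slope=d["slope"],
            intercept=d["intercept"],
            r_squared=d["r2"],
            x_units=d.get("x_units", "log10(fg/mL)"),
            x_range=tuple(d["x_range"]) if "x_range" in d else None,
        )


def fit_calibration(points: Sequence[CalibrationPoint]) -> CalibrationModel:
    """Ordinary least squares of dI on log10 concentration.

    Requires at least three points from a single analyte/matrix pair
    spanning at least two decades of concentration.
    """
    points = list(points)
    if len(points) < 3:
        raise ValueError(f"need >= 3 calibration points, got {len(points)}")
    pairs = {(p.analyte, p.matrix) for p in points}
    if len(pairs) != 1:
        raise ValueError(f"points mix analyte/matrix pairs: {sorted(pairs)}")
    x = np.log10([p.concentration for p in points])
    y = np.array([p.signal for p in points])
    span = x.max() - x.min()
    if span == 0:
        raise ValueError("zero variance in log10 concentration")
    if span < 2:
        raise ValueError(
            f"calibration must span >= 2 decades, got {span:.2f}"
        )
    res = stats.linregress(x, y)
    (analyte, matrix) = pairs.pop()
    return CalibrationModel(
        analyte=analyte,
        matrix=matrix,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        x_range=(float(x.min()), float(x.max())),
    )


def predict_signal(model: CalibrationModel, concentration: float) -> float:
    """Expected current drop dI (uA) at a concentration in fg/mL."""
    if concentration <= 0:
        raise ValueError(f"concentration must be positive, got {concentration}")
    return model.slope * math.log10(concentration) + model.intercept


def invert_concentration(model: CalibrationModel, I0: float, Ic: float) -> float:
    """Concentration (fg/mL) from a measured (I0, Ic) current pair.

    Exact inverse of :func:`predict_signal`.  A signal outside the
    calibrated range still returns a value but emits an
    :class:`ExtrapolationWarning` (time-course samples may fall below
    the calibrated floor).
    """
    if Ic >= I0:
        raise ValueError(
            f"response current Ic={Ic} uA not below baseline I0={I0} uA: "
            "no binding signal"
        )
    signal = I0 - Ic
    x = (signal - model.intercept) / model.slope
    if model.x_range is not None and not (
        model.x_range[0] <= x <= model.x_range[1]
    ):
        warnings.warn(
            f"signal {signal:.3g} uA maps to log10(conc) = {x:.3g}, outside "
            f"the calibrated range {model.x_range}",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return 10.0**x


def limit_of_detection(model: CalibrationModel, sigma_blank: float) -> float:
    """3-sigma limit of detection in fg/mL.

    The smallest concentration whose expected signal exceeds three times
    the blank current noise: ``10 ** ((3 sigma_blank - b) / a)``.
    """
    if sigma_blank < 0:
        raise ValueError("sigma_blank must be nonnegative")
    return 10.0 ** ((3.0 * sigma_blank - model.intercept) / model.slope)


def reference_model(analyte: str, matrix: str) -> CalibrationModel:
    """The published fit line for one analyte/matrix pair as a model."""
    try:
        a, b = REFERENCE_LINES[(analyte, matrix)]
    except KeyError:
        raise KeyError(
            f"no reference line for ({analyte}, {matrix}); known pairs: "
            f"{sorted(REFERENCE_LINES)}"
        ) from None
    return CalibrationModel(
        analyte=analyte,
        matrix=matrix,
        slope=a,
        intercept=b,
        r_squared=0.99,
        x_range=(2.0, 9.0),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_calibration_csv(path) -> list[CalibrationPoint]:
    """Read calibration points (analyte, matrix, conc_fg_ml, I0_uA, Ic_uA)."""
    df = pd.read_csv(path)
    required = {"analyte", "matrix", "conc_fg_ml", "I0_uA", "Ic_uA"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"calibration CSV missing columns: {sorted(missing)}")
    return [
        CalibrationPoint(
            analyte=row.analyte,
            matrix=row.matrix,
            concentration=row.conc_fg_ml,
            I0=row.I0_uA,
            Ic=row.Ic_uA,
        )
        for row in df.itertuples()
    ]


def calibration_frame(points: Iterable[CalibrationPoint]) -> pd.DataFrame:
    """Calibration points as the canonical CSV schema."""
    return pd.DataFrame(
        [
            {
                "analyte": p.analyte,
                "matrix": p.matrix,
                "conc_fg_ml": p.concentration,
                "I0_uA": p.I0,
                "Ic_uA": p.Ic,
            }
            for p in points
        ]
    )


def write_models_json(models: Iterable[CalibrationModel], path) -> None:
    payload = [m.to_dict() for m in models]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_models_json(path) -> list[CalibrationModel]:
    with open(path) as fh:
        payload = json.load(fh)
    return [CalibrationModel.from_dict(d) for d in payload]
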