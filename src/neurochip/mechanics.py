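"""Finite-strain extension-torsion mechanics of a cell-laden elastomer tube.

A soft cylindrical tube (PDMS, neuron-lined inner wall) is loaded under
displacement control with a nominal axial strain ``epsilon`` and a total
twist angle ``Psi``.  For an isotropic, homogeneous, incompressible
cylinder the deformation is known in closed form: the axial stretch is
``lambda = 1 + epsilon``, the twist per unit reference length is
``psi = Psi / L`` and material points map as

    (R, Theta, Z)  ->  (lambda^(-1/2) R, Theta + psi Z, lambda Z)

which gives a deformation gradient (cylindrical ordering R, Theta, Z)

    F = [[lambda^(-1/2), 0, 0],
         [0, lambda^(-1/2), psi R lambda^(-1/2)],
         [0, 0, lambda]]

with det F = 1 identically.  The radial direction is a principal
direction with stretch ``lambda^(-1/2)``; the two in-plane principal
stretches are the square roots of the eigenvalues of the lower 2x2 block
of C = F^T F and admit a closed form (see :func:`principal_stretches`).

Stresses follow a one-term incompressible Ogden energy in the ABAQUS
convention,

    W = (2 mu / alpha**2) * (l1**alpha + l2**alpha + l3**alpha - 3),

with the hydrostatic pressure eliminated through the zero-radial-stress
closure sigma_r = 0 (the tube surface is traction free and the wall is
thin relative to the stress variation), so that

    sigma_i = (2 mu / alpha) * (lambda_i**alpha - lambda_r**alpha).

Injury severity is stratified by the damage metric ``sigma_hat``, the
Euclidean norm of the principal Cauchy stresses, against a configurable
threshold (default 750 kPa).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TubeGeometry",
    "OgdenMaterial",
    "LoadingCondition",
    "DeformationState",
    "StressState",
    "axial_stretch",
    "twist_rate",
    "radial_map",
    "deformation_gradient",
    "right_cauchy_green",
    "principal_stretches",
    "principal_stretches_eigen",
    "biot_strains",
    "deformation_state",
    "ogden_principal_stresses",
    "damage_metric",
    "classify_severity",
    "default_loading_matrix",
    "sweep_loading_matrix",
    "SEVERITY_THRESHOLD_KPA",
]

#: Default damage-metric threshold separating sub- from supra-threshold
#: loading, in kPa.  Configurable throughout: the analytical homogeneous
#: model with the default shear modulus produces stresses far below the
#: finite-element scale at which this cut-off was originally defined, so
#: callers studying the analytic model may want a smaller value.
SEVERITY_THRESHOLD_KPA = 750.0

_SUB = "subthreshold"
_SUPRA = "suprathreshold"


@dataclass(frozen=True)
class TubeGeometry:
    """Reference geometry of the cylindrical culture tube (mm)."""

    L: float = 50.0
    R_int: float = 0.75
    R_ext: float = 2.5

    def __post_init__(self) -> None:
        if not (0 < self.R_int < self.R_ext):
            raise ValueError(
                f"require 0 < R_int < R_ext, got R_int={self.R_int}, R_ext={self.R_ext}"
            )
        if self.L <= 0:
            raise ValueError(f"gauge length must be positive, got L={self.L}")


@dataclass(frozen=True)
class OgdenMaterial:
    """One-term Ogden parameters: mu (kPa), alpha, volumetric compliance D.

    ``D`` (kPa^-1) is carried for completeness; the analytical model is
    fully incompressible and never uses it.
    """

    mu: float = 19.14
    alpha: float = 1.5
    D: float = 3e-8

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError(f"mu must be positive, got {self.mu}")
        if self.alpha == 0:
            raise ValueError("alpha must be nonzero")
        if self.D < 0:
            raise ValueError(f"D must be nonnegative, got {self.D}")


@dataclass(frozen=True)
class LoadingCondition:
    """One programmed mechanical insult: axial strain + total twist.

    ``epsilon`` is the nominal axial strain (0.04 means 4%), ``Psi_deg``
    the total twist angle in degrees.  ``(0, 0)`` is the static control.
    """

    epsilon: float
    Psi_deg: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")
        if self.Psi_deg < 0:
            raise ValueError(f"Psi_deg must be >= 0, got {self.Psi_deg}")
        if not self.label:
            object.__setattr__(self, "label", _default_label(self.key))

    @property
    def key(self) -> tuple[int, int]:
        """Canonical (extension %, torsion degrees) integer key."""
        return (round(self.epsilon * 100), round(self.Psi_deg))

    @property
    def is_static(self) -> bool:
        return self.epsilon == 0 and self.Psi_deg == 0


def _default_label(key: tuple[int, int]) -> str:
    ext, tor = key
    if ext == 0 and tor == 0:
        return "static"
    if tor == 0:
        return f"ext{ext}"
    if ext == 0:
        return f"tor{tor}"
    return f"ext{ext}_tor{tor}"


@dataclass(frozen=True)
class DeformationState:
    """Kinematic quantities at one radius for one loading condition."""

    lambda_ax: float
    psi: float
    R: float
    F: np.ndarray
    C: np.ndarray
    lambda_r: float
    lambda_1: float
    lambda_2: float
    eps_1: float
    eps_2: float


@dataclass(frozen=True)
class StressState:
    """Principal Cauchy stresses (kPa) and damage metric sigma_hat."""

    sigma_1: float
    sigma_2: float
    sigma_r: float
    sigma_hat: float
    severity: Optional[str] = None


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------

def axial_stretch(epsilon: float) -> float:
    """Axial stretch ``lambda = 1 + epsilon`` from nominal strain."""
    if epsilon <= -1:
        raise ValueError(
            f"nominal strain {epsilon} <= -1 implies non-physical collapse"
        )
    return 1.0 + epsilon


def twist_rate(Psi_deg: float, L: float) -> float:
    """Twist per unit reference length ``psi = Psi / L`` in rad/mm."""
    if L <= 0:
        raise ValueError(f"gauge length must be positive, got {L}")
    return math.radians(Psi_deg) / L


def radial_map(R: float, lambda_ax: float) -> float:
    """Deformed radius ``r = lambda^(-1/2) R`` (volume-preserving)."""
    if R < 0:
        raise ValueError(f"radius must be nonnegative, got {R}")
    return lambda_ax ** (-0.5) * R


def deformation_gradient(lambda_ax: float, psi: float, R: float) -> np.ndarray:
    """Deformation gradient F in cylindrical (R, Theta, Z) ordering."""
    if lambda_ax <= 0:
        raise ValueError(f"axial stretch must be positive, got {lambda_ax}")
    inv_sqrt = lambda_ax ** (-0.5)
    return np.array(
        [
            [inv_sqrt, 0.0, 0.0],
            [0.0, inv_sqrt, psi * R * inv_sqrt],
            [0.0, 0.0, lambda_ax],
        ]
    )


def right_cauchy_green(F: np.ndarray) -> np.ndarray:
    """Right Cauchy-Green tensor ``C = F^T F``."""
    F = np.asarray(F, dtype=float)
    if F.shape != (3, 3):
        raise ValueError(f"F must be 3x3, got shape {F.shape}")
    return F.T @ F


def principal_stretches(
    lambda_ax: float, psi: float, R: float
) -> tuple[float, float, float]:
    """Closed-form principal stretches ``(lambda_r, lambda_1, lambda_2)``.

    The radial direction is a principal direction with stretch
    ``lambda^(-1/2)``.  The in-plane stretches are the square roots of
    the eigenvalues of the 2x2 sub-block of C:

        lambda_{1,2}^2 = (T +/- sqrt(T^2 - 4 lambda^3)) / (2 lambda),
        T = lambda^3 + psi^2 R^2 + 1.

    ``lambda_1 >= lambda_2`` always; under any non-trivial load with
    ``lambda >= 1`` one has ``lambda_1 > 1 > lambda_2``.
    """
    if lambda_ax <= 0:
        raise ValueError(f"axial stretch must be positive, got {lambda_ax}")
    lam3 = lambda_ax**3
    T = lam3 + (psi * R) ** 2 + 1.0
    disc = T * T - 4.0 * lam3
    if disc < 0:
        # T^2 - 4 lambda^3 = (lambda^3 - 1)^2 + stuff >= 0 analytically;
        # only floating-point noise can push it below zero.
        if disc < -1e-12:
            raise ArithmeticError(
                f"negative discriminant {disc} for lambda={lambda_ax}, psiR={psi * R}"
            )
        disc = 0.0
    root = math.sqrt(disc)
    lam1 = math.sqrt((T + root) / (2.0 * lambda_ax))
    lam2 = math.sqrt((T - root) / (2.0 * lambda_ax))
    return (lambda_ax ** (-0.5), lam1, lam2)


def principal_stretches_eigen(C: np.ndarray) -> tuple[float, float, float]:
    """Principal stretches by numerical eigen-decomposition of C.

    Independent cross-check of :func:`principal_stretches`: the radial
    eigenvalue is identified through its eigenvector (aligned with e_R)
    and the remaining two are sorted descending.
    """
    C = np.asarray(C, dtype=float)
    if C.shape != (3, 3):
        raise ValueError(f"C must be 3x3, got shape {C.shape}")
    if not np.allclose(C, C.T, rtol=0, atol=1e-10):
        raise ValueError("C must be symmetric")
    evals, evecs = np.linalg.eigh(C)
    if np.any(evals <= 0):
        raise ValueError(f"C must be positive-definite, eigenvalues {evals}")
    radial_idx = int(np.argmax(np.abs(evecs[0, :])))
    lam_r = math.sqrt(evals[radial_idx])
    others = sorted(
        (math.sqrt(evals[i]) for i in range(3) if i != radial_idx), reverse=True
    )
    return (lam_r, others[0], others[1])


def biot_strains(lambda_1: float, lambda_2: float) -> tuple[float, float]:
    """Principal nominal (Biot) strains ``eps_i = lambda_i - 1``."""
    if lambda_1 <= 0 or lambda_2 <= 0:
        raise ValueError("stretches must be positive")
    return (lambda_1 - 1.0, lambda_2 - 1.0)


def deformation_state(
    condition: LoadingCondition,
    geometry: TubeGeometry = TubeGeometry(),
    R: Optional[float] = None,
) -> DeformationState:
    """Assemble the full kinematic state at radius ``R`` (default inner wall)."""
    R_eval = geometry.R_int if R is None else R
    lam = axial_stretch(condition.epsilon)
    psi = twist_rate(condition.Psi_deg, geometry.L)
    F = deformation_gradient(lam, psi, R_eval)
    C = right_cauchy_green(F)
    lam_r, lam1, lam2 = principal_stretches(lam, psi, R_eval)
    eps1, eps2 = biot_strains(lam1, lam2)
    return DeformationState(
        lambda_ax=lam,
        psi=psi,
        R=R_eval,
        F=F,
        C=C,
        lambda_r=lam_r,
        lambda_1=lam1,
        lambda_2=lam2,
        eps_1=eps1,
        eps_2=eps2,
    )


# ---------------------------------------------------------------------------
# Hyperelastic stresses
# ---------------------------------------------------------------------------

def ogden_principal_stresses(
    lambda_1: float,
    lambda_2: float,
    lambda_r: float,
    material: OgdenMaterial = OgdenMaterial(),
    threshold_kPa: Optional[float] = None,
) -> StressState:
    """Principal Cauchy stresses for the incompressible one-term Ogden solid.

    With the pressure eliminated by the zero-radial-stress closure:

        sigma_i = (2 mu / alpha) * (lambda_i**alpha - lambda_r**alpha),
        sigma_r = 0.

    Pure extension (``lambda_2 == lambda_r``) recovers the uniaxial state
    ``sigma_2 = 0`` exactly.  If ``threshold_kPa`` is given the severity
    class is attached to the returned state.
    """
    if min(lambda_1, lambda_2, lambda_r) <= 0:
        raise ValueError("stretches must be positive")
    J = lambda_1 * lambda_2 * lambda_r
    if abs(J - 1.0) > 1e-8:
        raise ValueError(
            f"incompressibility violated: lambda_1*lambda_2*lambda_r = {J}"
        )
    mu, alpha = material.mu, material.alpha
    coeff = 2.0 * mu / alpha
    p_term = lambda_r**alpha
    sigma_1 = coeff * (lambda_1**alpha - p_term)
    sigma_2 = coeff * (lambda_2**alpha - p_term)
    sigma_hat = math.hypot(sigma_1, sigma_2)
    severity = (
        classify_severity(sigma_hat, threshold_kPa)
        if threshold_kPa is not None
        else None
    )
    return StressState(
        sigma_1=sigma_1,
        sigma_2=sigma_2,
        sigma_r=0.0,
        sigma_hat=sigma_hat,
        severity=severity,
    )


def damage_metric(stress: StressState) -> float:
    """Damage metric: Euclidean norm of the principal Cauchy stresses."""
    return math.sqrt(
        stress.sigma_1**2 + stress.sigma_2**2 + stress.sigma_r**2
    )


def classify_severity(
    sigma_hat: float, threshold: float = SEVERITY_THRESHOLD_KPA
) -> str:
    """Binary severity: suprathreshold iff ``sigma_hat > threshold`` (kPa)."""
    if sigma_hat < 0:
        raise ValueError(f"sigma_hat must be nonnegative, got {sigma_hat}")
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    return _SUPRA if sigma_hat > threshold else _SUB


# ---------------------------------------------------------------------------
# Loading-matrix sweep
# ---------------------------------------------------------------------------

def default_loading_matrix(include_static: bool = True) -> list[LoadingCondition]:
    """The full programmed loading matrix.

    Extension 4-20% in 4% steps, torsion 30-300 degrees in 30-degree
    steps, combined 4-12% x 30-90 degrees, plus the static control:
    25 conditions in total.
    """
    conditions: list[LoadingCondition] = []
    if include_static:
        conditions.append(LoadingCondition(0.0, 0.0))
    conditions += [LoadingCondition(p / 100, 0.0) for p in range(4, 24, 4)]
    conditions += [LoadingCondition(0.0, d) for d in range(30, 330, 30)]
    conditions += [
        LoadingCondition(p / 100, d)
        for p in (4, 8, 12)
        for d in (30, 60, 90)
    ]
    return conditions


def sweep_loading_matrix(
    conditions: Iterable[LoadingCondition],
    geometry: TubeGeometry = TubeGeometry(),
    material: OgdenMaterial = OgdenMaterial(),
    evaluation_radius: Optional[float] = None,
    severity_threshold_kPa: float = SEVERITY_THRESHOLD_KPA,
) -> pd.DataFrame:
    """Kinematics + stresses for every condition, one row per condition.

    Evaluates at ``evaluation_radius`` (default: the inner wall, where the
    cells sit).  Deterministic; the row order follows the input order.
    """
    conditions = list(conditions)
    if not conditions:
        raise ValueError("condition list must be non-empty")
    rows = []
    for cond in conditions:
        state = deformation_state(cond, geometry, evaluation_radius)
        stress = ogden_principal_stresses(
            state.lambda_1,
            state.lambda_2,
            state.lambda_r,
            material,
            threshold_kPa=severity_threshold_kPa,
        )
        rows.append(
            {
                "condition_id": cond.label,
                "extension_pct": cond.key[0],
                "torsion_deg": cond.key[1],
                "lambda1": state.lambda_1,
                "lambda2": state.lambda_2,
                "eps1": state.eps_1,
                "eps2": state.eps_2,
                "sigma1_kPa": stress.sigma_1,
                "sigma2_kPa": stress.sigma_2,
                "sigma_hat_kPa": stress.sigma_hat,
                "severity": stress.severity,
            }
        )
    return pd.DataFrame(rows)


def read_loading_matrix(path) -> list[LoadingCondition]:
    """Read a loading matrix CSV (condition_id, extension_pct, torsion_deg)."""
    df = pd.read_csv(path)
    required = {"condition_id", "extension_pct", "torsion_deg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"loading matrix missing columns: {sorted(missing)}")
    return [
        LoadingCondition(
            epsilon=row.extension_pct / 100,
            Psi_deg=float(row.torsion_deg),
            label=str(row.condition_id),
        )
        for row in df.itertuples()
    ]
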