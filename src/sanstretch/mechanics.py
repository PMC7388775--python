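"""Passive tissue mechanics: stress, strain, and the exponential stiffness index.

Force/length measurements from an isometrically mounted SAN preparation are
converted to engineering stress and strain, and overall tissue stiffness is
summarised by the exponent beta of the exponential fit

    stress = alpha * exp(beta * strain)

where alpha (kPa) is the y-axis intercept and beta (dimensionless) the
stiffness index. The fit is nonlinear least squares in linear stress space,
initialised from the ordinary least-squares line through log(stress) vs
strain; the log-linear fit is also exposed as a diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "StressStrainCurve",
    "StiffnessFit",
    "to_stress",
    "to_strain",
    "fit_stiffness",
    "diastolic_force",
    "GRAMFORCE_TO_MN",
]

#: mN per gram-force (standard gravity); mN/mm^2 == kPa.
GRAMFORCE_TO_MN = 9.80665


@dataclass
class StressStrainCurve:
    """Paired stress-strain observations for one preparation."""

    strain: np.ndarray
    stress_kpa: np.ndarray
    l0_mm: float | None = None
    area_mm2: float | None = None

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress_kpa = np.asarray(self.stress_kpa, dtype=float)
        if self.strain.size == 0:
            raise ValueError("empty stress-strain curve")
        if self.strain.shape != self.stress_kpa.shape:
            raise ValueError("strain and stress must have equal length")
        if np.any(self.strain < 0):
            raise ValueError("strains must be >= 0")
        if np.any(np.diff(self.strain) <= 0):
            raise ValueError("strains must be strictly increasing")


@dataclass
class StiffnessFit:
    """Result of the exponential stiffness fit."""

    alpha_kpa: float
    beta: float
    rss_kpa2: float
    n_points: int
    exact_two_point: bool = False

    def predict(self, strain) -> np.ndarray:
        return self.alpha_kpa * np.exp(self.beta * np.asarray(strain, dtype=float))


def to_stress(force_gramforce, area_mm2: float):
    """Convert force (gram-force) to stress (kPa) over a cross-section (mm²)."""
    if area_mm2 <= 0:
        raise ValueError("cross-sectional area must be positive")
    return np.asarray(force_gramforce, dtype=float) * GRAMFORCE_TO_MN / area_mm2


def to_strain(length_mm, l0_mm: float):
    """Engineering strain (L - L0) / L0; negative values flagged with a warning."""
    if l0_mm <= 0:
        raise ValueError("baseline length must be positive")
    strain = (np.asarray(length_mm, dtype=float) - l0_mm) / l0_mm
    if np.any(strain < 0):
        warnings.warn("length below baseline: negative strain returned", stacklevel=2)
    return strain


def loglinear_init(strain: np.ndarray, stress: np.ndarray) -> tuple[float, float]:
    """OLS line through log(stress) vs strain -> (alpha, beta) initial values."""
    beta, log_alpha = np.polyfit(strain, np.log(stress), 1)
    return float(np.exp(log_alpha)), float(beta)


def fit_stiffness(curve: StressStrainCurve) -> StiffnessFit:
    """Fit stress = alpha * exp(beta * strain) by nonlinear least squares.

    Points with non-positive stress are excluded (with a warning). Two
    remaining points give the exact interpolating exponential, flagged via
    ``exact_two_point``; fewer than two is an error.
    """
    ok = curve.stress_kpa > 0
    if not np.all(ok):
        warnings.warn(
            f"excluded {int(np.sum(~ok))} non-positive stress point(s)", stacklevel=2
        )
    strain = curve.strain[ok]
    stress = curve.stress_kpa[ok]
    if strain.size < 2:
        raise ValueError("need >= 2 points with positive stress")

    if strain.size == 2:
        # exact closed form through two points
        beta = float(np.log(stress[1] / stress[0]) / (strain[1] - strain[0]))
        alpha = float(stress[0] * np.exp(-beta * strain[0]))
        return StiffnessFit(alpha, beta, 0.0, 2, exact_two_point=True)

    alpha0, beta0 = loglinear_init(strain, stress)
    try:
        (alpha, beta), _ = curve_fit(
            lambda x, a, b: a * np.exp(b * x),
            strain,
            stress,
            p0=(alpha0, beta0),
            maxfev=10000,
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"stiffness fit did not converge (init alpha={alpha0:.4g}, "
            f"beta={beta0:.4g}): {err}"
        ) from err
    resid = stress - alpha * np.exp(beta * strain)
    return StiffnessFit(float(alpha), float(beta), float(np.sum(resid**2)), int(strain.size))


def diastolic_force(force: np.ndarray, beat_indices: np.ndarray) -> np.ndarray:
    """Per-beat passive (diastolic) force: minimum between consecutive beats.

    ``beat_indices`` are sample indices of beat peaks in the force trace.
    """
    beat_indices = np.asarray(beat_indices, dtype=int)
    if beat_indices.size < 2:
        raise ValueError("need >= 2 beats to bracket diastolic intervals")
    return np.array(
        [
            float(np.min(force[a:b]))
            for a, b in zip(beat_indices[:-1], beat_indices[1:])
        ]
    )
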