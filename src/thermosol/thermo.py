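"""Ideal solubility, activity coefficients and apparent dissolution
thermodynamics.

The ideal solubility follows from fusion properties alone:

    ln x_idl = −ΔHfus·(Tfus − T)/(R·Tfus·T)
               + (ΔCp/R)·[(Tfus − T)/T + ln(T/Tfus)]

with ΔCp approximated by ΔHfus/Tfus. The activity coefficient γ = x_idl/x_e
then measures the departure of the real saturated solution from ideality
(γ < 1 indicates solute–solvent interactions stronger than in the ideal
solution).

Apparent dissolution thermodynamics come from a van't Hoff analysis centred
at the mean harmonic temperature Thm of the study window: ln x is regressed
on (1/T − 1/Thm), giving

    ΔH°sol = −R · slope,    ΔG°sol = −R · Thm · intercept,
    ΔS°sol = (ΔH°sol − ΔG°sol) / Thm.

Centring at Thm makes the intercept a free-energy estimate at a single
reference temperature and decorrelates slope and intercept over the narrow
experimental window. Enthalpy–entropy compensation is assessed by regressing
ΔH°sol on ΔG°sol across solvent compositions; a positive slope indicates
that the dissolution driving force is dominated by the enthalpy/entropy
trade-off of solvation rather than by a single interaction term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._utils import GAS_CONSTANT as R
from .exceptions import InsufficientDataError, InvalidInputError, OutOfDomainError
from .models import TemperatureSeries

__all__ = [
    "FusionProperties",
    "ThermoResult",
    "ActivityResult",
    "delta_cp",
    "ideal_solubility",
    "activity_coefficient",
    "harmonic_mean_temperature",
    "vanthoff_thermo",
    "compensation_analysis",
]


def delta_cp(dHfus: float, Tfus: float) -> float:
    """Fusion heat-capacity change ΔCp = ΔHfus / Tfus (J·mol⁻¹·K⁻¹)."""
    if dHfus <= 0 or Tfus <= 0:
        raise InvalidInputError("ΔHfus and Tfus must be positive")
    return dHfus / Tfus


@dataclass(frozen=True)
class FusionProperties:
    """Melting properties from DSC: Tfus in K, ΔHfus in J·mol⁻¹.

    ``dCp`` is derived as ΔHfus/Tfus and not independently settable.
    """

    Tfus: float
    dHfus: float
    dCp: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "dCp", delta_cp(self.dHfus, self.Tfus))


@dataclass(frozen=True)
class ThermoResult:
    """Apparent dissolution thermodynamics at the reference temperature Thm."""

    dH: float  # J·mol⁻¹
    dG: float  # J·mol⁻¹
    dS: float  # J·mol⁻¹·K⁻¹
    Thm: float  # K
    slope: float
    intercept: float


@dataclass(frozen=True)
class ActivityResult:
    x_ideal: float
    x_experimental: float
    gamma: float


def ideal_solubility(fusion: FusionProperties, T) -> np.ndarray | float:
    """Ideal mole-fraction solubility from fusion thermodynamics.

    Both terms vanish at T = Tfus, so x_idl(Tfus) = 1; values are clipped to
    at most 1 against rounding. Raises for T > Tfus (the solid no longer
    exists there).
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise InvalidInputError("temperature must be > 0 K")
    if np.any(T > fusion.Tfus):
        raise OutOfDomainError("ideal solubility is defined only for T <= Tfus")
    Tf = fusion.Tfus
    lnx = -fusion.dHfus * (Tf - T) / (R * Tf * T) + (fusion.dCp / R) * (
        (Tf - T) / T + np.log(T / Tf)
    )
    out = np.minimum(np.exp(lnx), 1.0)
    return float(out) if out.ndim == 0 else out


def activity_coefficient(x_ideal: float, x_exp: float) -> ActivityResult:
    """γ = x_idl / x_e."""
    if not 0.0 < x_ideal <= 1.0:
        raise InvalidInputError("x_ideal must lie in (0, 1]")
    if not 0.0 < x_exp <= 1.0:
        raise InvalidInputError("x_exp must lie in (0, 1]")
    return ActivityResult(
        x_ideal=x_ideal, x_experimental=x_exp, gamma=x_ideal / x_exp
    )


def harmonic_mean_temperature(temps) -> float:
    """Thm = n / Σ(1/Tᵢ)."""
    T = np.asarray(temps, dtype=float)
    if T.size == 0:
        raise InvalidInputError("temperature list must be nonempty")
    if np.any(T <= 0):
        raise InvalidInputError("temperatures must be positive")
    return float(T.size / np.sum(1.0 / T))


def vanthoff_thermo(series: TemperatureSeries, Thm: float) -> ThermoResult:
    """Van't Hoff thermodynamic decomposition of a solubility series."""
    if len(series) < 3:
        raise InsufficientDataError("thermodynamic analysis needs >= 3 points")
    if Thm <= 0:
        raise InvalidInputError("Thm must be > 0 K")
    z = 1.0 / series.temperatures - 1.0 / Thm
    X = np.column_stack([np.ones_like(z), z])
    beta, *_ = np.linalg.lstsq(X, np.log(series.x), rcond=None)
    intercept, slope = float(beta[0]), float(beta[1])
    dH = -R * slope
    dG = -R * Thm * intercept
    dS = (dH - dG) / Thm
    return ThermoResult(dH=dH, dG=dG, dS=dS, Thm=Thm, slope=slope, intercept=intercept)


def compensation_analysis(results) -> tuple[float, float]:
    """OLS of ΔH°sol on ΔG°sol across compositions → (slope, intercept).

    ``results`` is a sequence of (dH, dG) pairs or :class:`ThermoResult`
    objects. The slope sign carries the physical reading: positive means
    enthalpy and free energy co-vary (solvation-driven compensation).
    """
    pairs = [
        (r.dH, r.dG) if isinstance(r, ThermoResult) else (float(r[0]), float(r[1]))
        for r in results
    ]
    if len(pairs) < 2:
        raise InvalidInputError("compensation analysis needs >= 2 points")
    dH = np.array([p[0] for p in pairs])
    dG = np.array([p[1] for p in pairs])
    if np.ptp(dG) == 0:
        raise InvalidInputError("ΔG values have zero variance; slope undefined")
    X = np.column_stack([np.ones_like(dG), dG])
    beta, *_ = np.linalg.lstsq(X, dH, rcond=None)
    return float(beta[1]), float(beta[0])
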