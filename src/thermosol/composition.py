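"""Gravimetric-to-mole-fraction conversions for solubility experiments.

A saturated-solution aliquot is weighed, the solvent(s) evaporated and the
dissolved drug weighed back (or assayed); the measurement record is therefore
a set of masses plus molar masses. These helpers convert such records to the
mole-fraction solubility ``x`` used by every model in the package, and to the
solute-free cosolvent mass fraction ``w2`` that indexes binary-mixture data.

A note on naming: the composition fraction of a binary solvent is computed
here as a mass ratio, ``w2 = m2 / (m1 + m2)``. Parts of the cosolvency
literature label the same quantity a "mole fraction" while still computing
the mass ratio; this package keeps the arithmetic and treats ``w2`` as an
abstract solute-free composition fraction in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import InvalidInputError

__all__ = [
    "GravimetricRecord",
    "MixturePoint",
    "mole_fraction_single",
    "mole_fraction_ternary",
    "cosolvent_fraction",
]


@dataclass(frozen=True)
class GravimetricRecord:
    """One gravimetric solubility measurement.

    Masses are in grams (no unit inference), molar masses in g·mol⁻¹ and
    temperature in kelvin. ``mass_solvent2`` is zero for a single-solvent
    measurement.
    """

    mass_drug: float
    mass_solvent1: float
    mass_solvent2: float
    molar_mass_drug: float
    molar_mass_solvent1: float
    molar_mass_solvent2: float
    temperature: float

    def __post_init__(self) -> None:
        for name in ("mass_drug", "mass_solvent1", "mass_solvent2"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        for name in (
            "molar_mass_drug",
            "molar_mass_solvent1",
            "molar_mass_solvent2",
        ):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0")
        if self.temperature <= 0:
            raise InvalidInputError("temperature must be > 0 K")


@dataclass(frozen=True)
class MixturePoint:
    """Mole-fraction solubility at one (composition, temperature) point."""

    w2: float
    temperature: float
    x: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.w2 <= 1.0:
            raise InvalidInputError("w2 must lie in [0, 1]")
        if self.temperature <= 0:
            raise InvalidInputError("temperature must be > 0 K")
        if not 0.0 < self.x <= 1.0:
            raise InvalidInputError("mole fraction x must lie in (0, 1]")

    @property
    def w1(self) -> float:
        return 1.0 - self.w2


def mole_fraction_single(record: GravimetricRecord) -> float:
    """Mole-fraction solubility in a single solvent.

    x = (mA/MA) / (mA/MA + m1/M1).
    """
    if record.mass_solvent2 != 0:
        raise InvalidInputError(
            "mass_solvent2 must be 0 for a single-solvent record; "
            "use mole_fraction_ternary for mixtures"
        )
    if record.mass_solvent1 <= 0:
        raise InvalidInputError("mass_solvent1 must be > 0")
    n_drug = record.mass_drug / record.molar_mass_drug
    n_solv = record.mass_solvent1 / record.molar_mass_solvent1
    return n_drug / (n_drug + n_solv)


def mole_fraction_ternary(record: GravimetricRecord) -> float:
    """Mole-fraction solubility in a binary solvent mixture.

    x = (mA/MA) / (mA/MA + m1/M1 + m2/M2). With ``mass_solvent2 == 0`` this
    reduces exactly to :func:`mole_fraction_single`.
    """
    if record.mass_solvent1 <= 0 and record.mass_solvent2 <= 0:
        raise InvalidInputError("at least one solvent mass must be > 0")
    n_drug = record.mass_drug / record.molar_mass_drug
    n1 = record.mass_solvent1 / record.molar_mass_solvent1
    n2 = record.mass_solvent2 / record.molar_mass_solvent2
    return n_drug / (n_drug + n1 + n2)


def cosolvent_fraction(mass_solvent2: float, mass_solvent1: float) -> float:
    """Solute-free cosolvent mass fraction w2 = m2 / (m1 + m2)."""
    if mass_solvent1 < 0 or mass_solvent2 < 0:
        raise InvalidInputError("masses must be >= 0")
    total = mass_solvent1 + mass_solvent2
    if total <= 0:
        raise InvalidInputError("m1 + m2 must be > 0")
    return mass_solvent2 / total
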