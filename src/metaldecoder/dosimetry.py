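"""Unit conversions between salt mass concentration, ion molarity and dose.

The exposure ladders are prepared gravimetrically (g/L of NaAsO2 or
K2Cr2O7) but interpreted as ion molarities, and regulatory limits are
quoted as ug/L of the *element*; this module holds the exact arithmetic
connecting the three, plus the ions-per-bacterium dosimetry that puts a
limit of detection in biological context.

Note the dichromate stoichiometry: one formula unit of K2Cr2O7 carries two
Cr6+ ions, so the ion molarity is twice the salt molarity.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "SaltSpec",
    "CultureSpec",
    "SALTS",
    "AVOGADRO",
    "mass_to_molar",
    "molar_to_mass",
    "ions_per_cell",
]

AVOGADRO = 6.02214e23  # mol^-1


@dataclass(frozen=True)
class SaltSpec:
    """Molar masses and stoichiometry of one dosing salt."""

    name: str
    molar_mass: float  # g/mol of the salt
    ions_per_formula: int  # metal ions released per formula unit
    element_mass: float  # g/mol of the metal element

    def __post_init__(self) -> None:
        if self.molar_mass <= self.element_mass:
            raise ValueError("salt molar mass must exceed the element mass")
        if self.ions_per_formula < 1:
            raise ValueError("ions_per_formula must be >= 1")


SALTS: dict[str, SaltSpec] = {
    "NaAsO2": SaltSpec("NaAsO2", molar_mass=129.91, ions_per_formula=1, element_mass=74.92),
    "K2Cr2O7": SaltSpec("K2Cr2O7", molar_mass=294.18, ions_per_formula=2, element_mass=52.00),
}


@dataclass(frozen=True)
class CultureSpec:
    """Culture density model: cells/mL = od * cells_per_ml_per_od.

    The default calibration of 1e9 cells/mL per OD unit (5e8 cells/mL at
    OD 0.5) is inferred, not measured: it is the round-number factor
    consistent with the study's printed ions-per-bacterium ratios.
    """

    od: float = 0.5
    cells_per_ml_per_od: float = 1e9

    def __post_init__(self) -> None:
        if self.od < 0:
            raise ValueError("od must be nonnegative")


def _lookup(salt: str | SaltSpec) -> SaltSpec:
    if isinstance(salt, SaltSpec):
        return salt
    try:
        return SALTS[salt]
    except KeyError:
        raise ValueError(f"unknown salt {salt!r} (known: {sorted(SALTS)})") from None


def mass_to_molar(mass_conc: float, salt: str | SaltSpec, basis: str = "ion") -> float:
    """Convert g/L to mol/L on the requested basis.

    ``salt``: moles of formula units; ``ion``: metal-ion molarity (salt
    molarity times stoichiometry); ``element``: for limits quoted as mass of
    the bare element (e.g. WHO's 10 ug/L As), mass over the element's molar
    mass.
    """
    if mass_conc < 0:
        raise ValueError("mass concentration must be nonnegative")
    spec = _lookup(salt)
    if basis == "salt":
        return mass_conc / spec.molar_mass
    if basis == "ion":
        return mass_conc / spec.molar_mass * spec.ions_per_formula
    if basis == "element":
        return mass_conc / spec.element_mass
    raise ValueError("basis must be 'salt', 'ion' or 'element'")


def molar_to_mass(molarity: float, salt: str | SaltSpec, basis: str = "ion") -> float:
    """Inverse of :func:`mass_to_molar` (exact round-trip)."""
    if molarity < 0:
        raise ValueError("molarity must be nonnegative")
    spec = _lookup(salt)
    if basis == "salt":
        return molarity * spec.molar_mass
    if basis == "ion":
        return molarity / spec.ions_per_formula * spec.molar_mass
    if basis == "element":
        return molarity * spec.element_mass
    raise ValueError("basis must be 'salt', 'ion' or 'element'")


def ions_per_cell(molarity: float, culture: CultureSpec = CultureSpec()) -> float:
    """Metal ions per bacterium in solution at the given ion molarity.

    ``(molarity * N_A / 1000 mL) / (od * cells_per_ml_per_od)`` — i.e. ions
    per mL over cells per mL.
    """
    if molarity < 0:
        raise ValueError("molarity must be nonnegative")
    if culture.od == 0:
        raise ValueError("od must be positive for a per-cell dose")
    ions_per_ml = molarity * AVOGADRO / 1000.0
    cells_per_ml = culture.od * culture.cells_per_ml_per_od
    return ions_per_ml / cells_per_ml
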