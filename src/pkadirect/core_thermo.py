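"""Direct-approach dissociation thermodynamics.

The pKa of a phenol HA is computed from the charge-conserving exchange with
hydroxide, each species carrying the same number ``n`` of explicit water
molecules inside a continuum solvent::

    HA(H2O)n + OH-(H2O)n  <=>  A-(H2O)n + H2O(H2O)n

The reaction electronic energy is

    dE_dep = E(A-) + E(H2O) - E(OH-) - E(HA)     [kcal/mol]

and the pKa follows from the affine map

    pKa = dE_dep / (ln10 * R * T) + C

with C = 15.74 (the pKa of water on the molar scale at 298.15 K, which is
what the hydroxide reference reaction leaves behind). No fitted correction
factors enter anywhere: the offset is a protocol constant, not a regression
intercept.

Electronic energies (not thermally corrected free energies) enter the
reaction energy by default; an optional ``free_energy`` field on
:class:`EnergyRecord` is carried through but ignored by this pathway.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

from .errors import (
    AssemblyError,
    InvalidConstantsError,
    InvalidValueError,
    StoichiometryError,
)

__all__ = [
    "Role",
    "Constants",
    "EnergyRecord",
    "DissociationSystem",
    "PkaResult",
    "hartree_to_kcalmol",
    "reaction_energy",
    "pka_from_reaction_energy",
    "reaction_energy_from_pka",
    "compute_pka",
]

#: kcal/mol per Hartree
HARTREE_TO_KCALMOL = 627.5095

#: gas constant, kcal mol^-1 K^-1
GAS_CONSTANT_KCAL = 1.987204259e-3


class Role(str, enum.Enum):
    """The four species of the hydroxide-exchange dissociation reaction."""

    HA = "HA"
    A_MINUS = "A_minus"
    OH_MINUS = "OH_minus"
    WATER = "WATER"


@dataclass(frozen=True)
class Constants:
    """Thermodynamic constants of the pKa protocol.

    Parameters
    ----------
    R : float
        Gas constant in kcal mol^-1 K^-1.
    T : float
        Temperature in K. The protocol convention is 298.15 K.
    ln10 : float
        Natural log of 10. Full precision by default; use
        :meth:`truncated_ln10` to reproduce the literature habit of
        writing "2.302" (difference below 0.002 pKa for benchmark-scale
        energies).
    C_offset : float
        Dimensionless additive constant of the pKa equation (15.74). A
        protocol constant, never fitted.
    hartree_to_kcalmol : float
        Energy conversion factor, kcal/mol per Hartree.
    """

    R: float = GAS_CONSTANT_KCAL
    T: float = 298.15
    ln10: float = math.log(10.0)
    C_offset: float = 15.74
    hartree_to_kcalmol: float = HARTREE_TO_KCALMOL

    def __post_init__(self) -> None:
        if not (self.R > 0.0) or not math.isfinite(self.R):
            raise InvalidConstantsError(f"gas constant must be positive, got {self.R}")
        if not (self.T > 0.0) or not math.isfinite(self.T):
            raise InvalidConstantsError(f"temperature must be positive, got {self.T} K")
        if not (self.hartree_to_kcalmol > 0.0):
            raise InvalidConstantsError(
                f"hartree_to_kcalmol must be positive, got {self.hartree_to_kcalmol}"
            )
        if not (self.ln10 > 0.0):
            raise InvalidConstantsError(f"ln10 must be positive, got {self.ln10}")

    @classmethod
    def truncated_ln10(cls, **overrides: float) -> "Constants":
        """Constants with ln10 truncated to 2.302, as often printed."""
        overrides.setdefault("ln10", 2.302)
        return cls(**overrides)

    @property
    def kcal_per_pka_unit(self) -> float:
        """ln10*R*T — reaction energy per pKa unit, kcal/mol."""
        return self.ln10 * self.R * self.T


@dataclass(frozen=True)
class EnergyRecord:
    """Electronic energy of one species at a fixed explicit-water count.

    ``energy`` is in Hartree, as emitted by QC engines. ``free_energy``
    (also Hartree) may carry a thermally corrected value; the default
    protocol ignores it.
    """

    role: Role
    label: str
    n_waters: int
    energy: float
    source: str = "synthetic"
    free_energy: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "role", Role(self.role))
        if self.n_waters < 0:
            raise InvalidValueError(
                f"n_waters must be non-negative, got {self.n_waters} for {self.label!r}"
            )
        if not math.isfinite(self.energy):
            raise InvalidValueError(
                f"energy must be finite, got {self.energy!r} for {self.label!r}"
            )


@dataclass(frozen=True)
class DissociationSystem:
    """The four-species assembly of the hydroxide-exchange reaction at fixed n."""

    ha: EnergyRecord
    a_minus: EnergyRecord
    oh_minus: EnergyRecord
    water: EnergyRecord
    n: int

    def __post_init__(self) -> None:
        expected = {
            "ha": Role.HA,
            "a_minus": Role.A_MINUS,
            "oh_minus": Role.OH_MINUS,
            "water": Role.WATER,
        }
        for attr, role in expected.items():
            rec: EnergyRecord = getattr(self, attr)
            if rec.role is not role:
                raise AssemblyError(
                    f"field {attr!r} must hold a {role.value} record, got {rec.role.value}"
                )
        counts = {attr: getattr(self, attr).n_waters for attr in expected}
        if any(c != self.n for c in counts.values()):
            raise StoichiometryError(
                f"all species must carry n_waters == {self.n}, got {counts}"
            )

    @property
    def records(self) -> tuple[EnergyRecord, EnergyRecord, EnergyRecord, EnergyRecord]:
        return (self.ha, self.a_minus, self.oh_minus, self.water)


@dataclass(frozen=True)
class PkaResult:
    """Reaction energy (kcal/mol), the resulting pKa, and the constants used."""

    delta_E_dep: float
    pka: float
    constants_used: Constants = field(default_factory=Constants)

    def __post_init__(self) -> None:
        c = self.constants_used
        expected = self.delta_E_dep / c.kcal_per_pka_unit + c.C_offset
        if abs(expected - self.pka) > 1e-12 * max(1.0, abs(expected)):
            raise InvalidValueError(
                f"inconsistent PkaResult: pka={self.pka} but constants give {expected}"
            )


def hartree_to_kcalmol(e: float, c: Constants | None = None) -> float:
    """Convert an energy from Hartree to kcal/mol."""
    if not math.isfinite(e):
        raise InvalidValueError(f"energy must be finite, got {e!r}")
    c = c or Constants()
    return e * c.hartree_to_kcalmol


def reaction_energy(sys: DissociationSystem, c: Constants | None = None) -> float:
    """Deprotonation reaction energy dE_dep in kcal/mol.

    dE_dep = E(A-) + E(H2O) - E(OH-) - E(HA), inputs in Hartree.
    """
    c = c or Constants()
    d_hartree = (
        sys.a_minus.energy + sys.water.energy - sys.oh_minus.energy - sys.ha.energy
    )
    return hartree_to_kcalmol(d_hartree, c)


def pka_from_reaction_energy(dE: float, c: Constants | None = None) -> float:
    """pKa from the reaction energy (kcal/mol): dE/(ln10*R*T) + C_offset."""
    if not math.isfinite(dE):
        raise InvalidValueError(f"reaction energy must be finite, got {dE!r}")
    c = c or Constants()
    return dE / c.kcal_per_pka_unit + c.C_offset


def reaction_energy_from_pka(pka: float, c: Constants | None = None) -> float:
    """Exact inverse of :func:`pka_from_reaction_energy` (kcal/mol)."""
    if not math.isfinite(pka):
        raise InvalidValueError(f"pka must be finite, got {pka!r}")
    c = c or Constants()
    return (pka - c.C_offset) * c.kcal_per_pka_unit


def compute_pka(sys: DissociationSystem, c: Constants | None = None) -> PkaResult:
    """Full pipeline: reaction energy of the four-species system, then pKa."""
    c = c or Constants()
    dE = reaction_energy(sys, c)
    return PkaResult(delta_E_dep=dE, pka=pka_from_reaction_energy(dE, c), constants_used=c)


def with_temperature(c: Constants, T: float) -> Constants:
    """A copy of ``c`` at a different temperature."""
    return replace(c, T=T)
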