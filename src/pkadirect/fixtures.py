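"""Synthetic stand-ins for QC-engine output.

Real inputs to the pKa pipeline are DFT logs that take hours of engine time
to produce. This module manufactures consistent substitutes so the whole
pipeline is exercisable in milliseconds:

* :func:`make_energy_set` inverts the pKa equation to produce four species
  energies whose reaction energy reproduces a chosen target pKa exactly;
  magnitudes are realistic (hundreds of Hartree with milli-Hartree
  differences) so floating-point cancellation bugs cannot hide;
* :func:`make_mock_log` writes a Gaussian-style text log that the qc_io
  parser round-trips (energy, frequencies, geometry, termination flag);
* :func:`phenol_template`, :func:`water_template` and
  :func:`hydroxide_template` are idealized tagged geometries for the
  microsolvation rules.

All randomness flows through one seeded generator per call; there is no
global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_thermo import (
    Constants,
    DissociationSystem,
    EnergyRecord,
    Role,
    reaction_energy_from_pka,
)
from .geometry import Geometry

__all__ = [
    "FixtureSpec",
    "make_energy_set",
    "make_mock_log",
    "mock_log_from_deck",
    "phenol_template",
    "water_template",
    "hydroxide_template",
]

# plausible electronic-energy anchors, Hartree
_OH_ANCHOR = -75.90
_WATER_ANCHOR = -76.45


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic energy quadruple."""

    target_pka: float
    n_waters: int = 2
    seed: int = 0
    base_energy: float = -308.0  # HA anchor, Hartree (phenol-with-waters scale)


def make_energy_set(spec: FixtureSpec, c: Constants | None = None) -> DissociationSystem:
    """Four species energies whose reaction energy yields ``target_pka``.

    Three energies are drawn near realistic anchors (seeded milli-Hartree
    jitter); the fourth is solved from the inverted pKa equation, so the
    round trip through reaction_energy and pka_from_reaction_energy is
    exact to floating-point resolution.
    """
    c = c or Constants()
    rng = np.random.default_rng(spec.seed)
    dE_hartree = reaction_energy_from_pka(spec.target_pka, c) / c.hartree_to_kcalmol
    jitter = rng.normal(scale=5e-3, size=3)
    e_ha = spec.base_energy + float(jitter[0])
    e_oh = _OH_ANCHOR + float(jitter[1])
    e_water = _WATER_ANCHOR + float(jitter[2])
    e_a = dE_hartree + e_oh + e_ha - e_water

    def rec(role: Role, label: str, energy: float) -> EnergyRecord:
        return EnergyRecord(
            role=role, label=label, n_waters=spec.n_waters, energy=energy, source="synthetic"
        )

    return DissociationSystem(
        ha=rec(Role.HA, f"HA(pKa={spec.target_pka})", e_ha),
        a_minus=rec(Role.A_MINUS, "A-", e_a),
        oh_minus=rec(Role.OH_MINUS, "OH-", e_oh),
        water=rec(Role.WATER, "H2O", e_water),
        n=spec.n_waters,
    )


_LOG_HEADER = " Entering Gaussian System, Link 0=g16\n"


def make_mock_log(
    energy: float,
    frequencies: list[float] | tuple[float, ...] = (),
    geometry: Geometry | None = None,
    converged: bool = True,
    route: str = "#p CAM-B3LYP/6-311+G(d,p) opt freq scrf=(smd,solvent=water)",
    extra_scf_energies: list[float] | tuple[float, ...] = (),
) -> str:
    """A Gaussian-style text log the qc_io parser round-trips exactly.

    ``extra_scf_energies`` are printed BEFORE the final ``energy`` so the
    last-SCF-wins rule is exercisable.
    """
    from .geometry import ATOMIC_NUMBERS

    lines = [_LOG_HEADER.rstrip("\n"), f" {route}", ""]
    if geometry is not None:
        dash = " " + "-" * 69
        lines += [
            "                         Standard orientation:",
            dash,
            " Center     Atomic      Atomic             Coordinates (Angstroms)",
            " Number     Number       Type             X           Y           Z",
            dash,
        ]
        for i, (el, (x, y, z)) in enumerate(zip(geometry.elements, geometry.coords), start=1):
            z_num = ATOMIC_NUMBERS.get(el, 0)
            lines.append(f" {i:6d} {z_num:10d} {0:11d} {x:15.6f} {y:11.6f} {z:11.6f}")
        lines.append(dash)
    for e in list(extra_scf_energies) + [energy]:
        lines.append(f" SCF Done:  E(RCAM-B3LYP) = {e:18.9f}     A.U. after   11 cycles")
    if frequencies:
        for start in range(0, len(frequencies), 3):
            chunk = frequencies[start : start + 3]
            lines.append(" Frequencies --  " + "  ".join(f"{f:12.4f}" for f in chunk))
    if converged:
        lines.append(" Normal termination of Gaussian 16 at Mon Jan  1 00:00:00 2024.")
    return "\n".join(lines) + "\n"


def mock_log_from_deck(deck: str, energy: float, **kwargs) -> str:
    """Read the coordinates out of an input deck and emit a mock log for them."""
    lines = deck.splitlines()
    coords: list[list[float]] = []
    elements: list[str] = []
    seen_charge = False
    for line in lines:
        parts = line.split()
        if not seen_charge:
            if len(parts) == 2 and all(_is_int(p) for p in parts):
                seen_charge = True
            continue
        if len(parts) >= 4:
            elements.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
    g = Geometry(elements=tuple(elements), coords=np.array(coords).reshape(-1, 3))
    return make_mock_log(energy, geometry=g, **kwargs)


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def phenol_template() -> Geometry:
    """Idealized 13-atom phenol with standard bond lengths, OH tagged.

    Planar C6 ring (C-C 1.39 A), ring hydrogens at 1.08 A, C-O 1.36 A,
    O-H 0.96 A with a 109 deg C-O-H angle. Index 6 is the phenolic O,
    index 7 the phenolic H.
    """
    rc, rch, rco, roh = 1.39, 1.08, 1.36, 0.96
    elements: list[str] = []
    coords: list[list[float]] = []
    ring = []
    for k in range(6):
        a = math.radians(60.0 * k)
        ring.append((rc * math.cos(a), rc * math.sin(a), 0.0))
        elements.append("C")
        coords.append(list(ring[-1]))
    # phenolic O on C0 (outward along +x)
    o_pos = (rc + rco, 0.0, 0.0)
    elements.append("O")
    coords.append(list(o_pos))
    # phenolic H: C-O-H = 109 deg, in plane
    ang = math.radians(180.0 - 109.0)
    h_pos = (o_pos[0] + roh * math.cos(ang), roh * math.sin(ang), 0.0)
    elements.append("H")
    coords.append(list(h_pos))
    # ring hydrogens on C1..C5, radially outward
    for k in range(1, 6):
        x, y, _ = ring[k]
        norm = math.hypot(x, y)
        elements.append("H")
        coords.append([x * (norm + rch) / norm, y * (norm + rch) / norm, 0.0])
    return Geometry(
        elements=tuple(elements),
        coords=np.array(coords),
        phenolic_o=6,
        phenolic_h=7,
        comment="idealized phenol template",
    )


def water_template() -> Geometry:
    """A single water, O-H tagged so the placement rules can hydrate it."""
    r, half = 0.9572, math.radians(104.52) / 2.0
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [r * math.cos(half), r * math.sin(half), 0.0],
            [r * math.cos(half), -r * math.sin(half), 0.0],
        ]
    )
    return Geometry(
        elements=("O", "H", "H"), coords=coords, phenolic_o=0, phenolic_h=1,
        comment="water template",
    )


def hydroxide_template() -> Geometry:
    """Hydroxide anion, O-H tagged."""
    coords = np.array([[0.0, 0.0, 0.0], [0.97, 0.0, 0.0]])
    return Geometry(
        elements=("O", "H"), coords=coords, phenolic_o=0, phenolic_h=1,
        comment="hydroxide template",
    )
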