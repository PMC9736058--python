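"""Quantum-chemistry plumbing: log parsing, energy tables, input decks.

The pKa protocol needs four electronic energies per compound (acid,
conjugate base, hydroxide and water, each with the same number of explicit
waters). This module moves those numbers in and out of the external QC
engine's world:

* :func:`parse_qc_output` reads a Gaussian-style text log, taking the LAST
  SCF energy in the file (optimizations print one per step), the harmonic
  frequencies when present, the final Cartesian geometry, and the
  normal-termination flag;
* :func:`read_energy_table` / :func:`write_energy_table` handle a plain CSV
  of species energies for engines the parser does not know;
* :func:`write_input_deck` emits a job deck for a registered
  functional/basis/solvation combination;
* :func:`assemble_system` turns four parsed calculations into a
  :class:`~pkadirect.core_thermo.DissociationSystem`, refusing species that
  failed the true-minimum check (imaginary frequencies).
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .core_thermo import DissociationSystem, EnergyRecord, Role
from .errors import (
    ConfigError,
    ParseError,
    ProtocolViolationError,
    SchemaError,
    StoichiometryError,
)
from .geometry import ELEMENT_SYMBOLS, Geometry

__all__ = [
    "ParsedCalculation",
    "ProtocolSpec",
    "RouteMetadata",
    "parse_qc_output",
    "validate_minimum",
    "read_energy_table",
    "write_energy_table",
    "write_input_deck",
    "assemble_system",
    "REGISTERED_FUNCTIONALS",
    "REGISTERED_SOLVATION",
]

REGISTERED_FUNCTIONALS: set[str] = {"B3LYP", "B3PW91", "wB97XD", "CAM-B3LYP"}
REGISTERED_SOLVATION: set[str] = {"SMD", "CPCM", "IEFPCM", "none"}

#: accepted aliases -> canonical labels
_SOLVATION_ALIASES = {"PCM": "IEFPCM", "NONE": "none", "": "none"}
_BASIS_ALIASES = {
    "6-311G+dp": "6-311+G(d,p)",
    "6-311g+dp": "6-311+G(d,p)",
    "6-311+g(d,p)": "6-311+G(d,p)",
}

ENERGY_TABLE_HEADER = ["label", "role", "n_waters", "energy_hartree", "source"]


def register_functional(name: str) -> None:
    REGISTERED_FUNCTIONALS.add(name)


def canonical_basis(label: str) -> str:
    """Normalize basis spellings (e.g. '6-311G+dp' -> '6-311+G(d,p)')."""
    return _BASIS_ALIASES.get(label, _BASIS_ALIASES.get(label.lower(), label))


def canonical_solvation(label: str) -> str:
    lab = _SOLVATION_ALIASES.get(label.upper(), label)
    for reg in REGISTERED_SOLVATION:
        if lab.lower() == reg.lower():
            return reg
    raise ConfigError(
        f"unregistered solvation model {label!r}; known: {sorted(REGISTERED_SOLVATION)}"
    )


@dataclass(frozen=True)
class RouteMetadata:
    functional: str | None = None
    basis: str | None = None
    solvation: str | None = None
    solvent: str | None = None


@dataclass(frozen=True)
class ParsedCalculation:
    """What one QC log yields: last SCF energy, frequencies, final geometry."""

    final_energy: float | None
    frequencies: tuple[float, ...]
    converged: bool
    geometry: Geometry | None
    route_metadata: RouteMetadata = field(default_factory=RouteMetadata)
    source: str = "<stream>"


@dataclass(frozen=True)
class ProtocolSpec:
    """One cell of the protocol grid: functional x basis x solvation x n."""

    functional: str = "CAM-B3LYP"
    basis: str = "6-311+G(d,p)"
    solvation: str = "SMD"
    solvent: str = "water"
    n_waters: int = 2
    charge: int = 0
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.functional not in REGISTERED_FUNCTIONALS:
            raise ConfigError(
                f"unregistered functional {self.functional!r}; "
                f"known: {sorted(REGISTERED_FUNCTIONALS)}"
            )
        object.__setattr__(self, "basis", canonical_basis(self.basis))
        object.__setattr__(self, "solvation", canonical_solvation(self.solvation))
        if self.multiplicity < 1:
            raise ConfigError(f"multiplicity must be >= 1, got {self.multiplicity}")
        if self.n_waters < 0:
            raise ConfigError(f"n_waters must be >= 0, got {self.n_waters}")


_SCF_RE = re.compile(r"SCF Done:\s+E\([^)]*\)\s*=\s*(-?\d+\.\d+)")
_FREQ_RE = re.compile(r"^\s*Frequencies\s*--\s*(.*)$")
_TERMINATION_RE = re.compile(r"Normal termination")
_ORIENTATION_RE = re.compile(r"(Standard|Input) orientation:")
_ROUTE_RE = re.compile(r"^\s*#")


def _parse_route(line: str) -> RouteMetadata:
    functional = basis = solvation = solvent = None
    m = re.search(r"scrf=\(([^)]*)\)", line, re.IGNORECASE)
    if m:
        parts = [p.strip() for p in m.group(1).split(",")]
        for p in parts:
            if p.lower().startswith("solvent="):
                solvent = p.split("=", 1)[1]
            elif p:
                try:
                    solvation = canonical_solvation(p)
                except ConfigError:
                    pass
    mm = re.search(r"(\S+)/(\S+)", line)
    if mm:
        cand_f, cand_b = mm.group(1).lstrip("#pPnNtT "), mm.group(2)
        for f in REGISTERED_FUNCTIONALS:
            if cand_f.lower() == f.lower():
                functional = f
                break
        basis = canonical_basis(cand_b)
    return RouteMetadata(functional=functional, basis=basis, solvation=solvation, solvent=solvent)


def _parse_orientation(lines: list[str], start: int, source: str) -> tuple[Geometry, int]:
    """Parse one coordinate table starting at its header line index."""
    i = start + 1
    dashes = 0
    elements: list[str] = []
    coords: list[list[float]] = []
    while i < len(lines):
        if set(lines[i].strip()) == {"-"} and lines[i].strip():
            dashes += 1
            if dashes == 3:
                return (
                    Geometry(elements=tuple(elements), coords=np.array(coords).reshape(-1, 3)),
                    i,
                )
            i += 1
            continue
        if dashes == 2:
            parts = lines[i].split()
            if len(parts) < 6:
                raise ParseError(
                    f"{source}: truncated coordinate table at line {i + 1}"
                )
            z = int(parts[1])
            elements.append(ELEMENT_SYMBOLS.get(z, f"X{z}"))
            coords.append([float(parts[-3]), float(parts[-2]), float(parts[-1])])
        i += 1
    raise ParseError(f"{source}: coordinate table starting at line {start + 1} is truncated")


def parse_qc_output(text: str | Iterable[str], source: str = "<stream>") -> ParsedCalculation:
    """Parse a Gaussian-style output log.

    Raises :class:`ParseError` when no SCF energy line is present or a
    coordinate table is cut off mid-file.
    """
    if isinstance(text, str):
        lines = text.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in text]
    if not lines or not any(ln.strip() for ln in lines):
        raise ParseError(f"{source}: empty stream")

    energies: list[float] = []
    freqs: list[float] = []
    geometry: Geometry | None = None
    route = RouteMetadata()
    converged = False
    for idx, line in enumerate(lines):
        m = _SCF_RE.search(line)
        if m:
            energies.append(float(m.group(1)))
            continue
        m = _FREQ_RE.match(line)
        if m:
            freqs.extend(float(v) for v in m.group(1).split())
            continue
        if _ORIENTATION_RE.search(line):
            geometry, _ = _parse_orientation(lines, idx, source)
            continue
        if _TERMINATION_RE.search(line):
            converged = True
            continue
        if _ROUTE_RE.match(line) and route == RouteMetadata():
            route = _parse_route(line)
    if not energies:
        raise ParseError(f"{source}: no SCF energy line found")
    return ParsedCalculation(
        final_energy=energies[-1],
        frequencies=tuple(freqs),
        converged=converged,
        geometry=geometry,
        route_metadata=route,
        source=source,
    )


def validate_minimum(calc: ParsedCalculation, tol: float = 0.0) -> bool | None:
    """True-minimum check: every harmonic frequency must be >= -tol cm^-1.

    Returns ``True`` (all real within tolerance), ``False`` (imaginary mode
    present) or ``None`` when the log carries no frequency block — no data,
    no claim.
    """
    if not calc.frequencies:
        return None
    return all(f >= -tol for f in calc.frequencies)


def read_energy_table(path: str | Path) -> list[EnergyRecord]:
    """Read species energies from CSV (label,role,n_waters,energy_hartree,source)."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file")
        missing = [c for c in ENERGY_TABLE_HEADER[:4] if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing columns {missing}")
        records: list[EnergyRecord] = []
        for rownum, row in enumerate(reader, start=2):
            try:
                role = Role(row["role"])
            except ValueError as exc:
                raise SchemaError(
                    f"{path}:{rownum}: unknown role {row['role']!r}; "
                    f"expected one of {[r.value for r in Role]}"
                ) from exc
            try:
                n_waters = int(row["n_waters"])
                energy = float(row["energy_hartree"])
            except (TypeError, ValueError) as exc:
                raise SchemaError(f"{path}:{rownum}: non-numeric field: {exc}") from exc
            if not math.isfinite(energy):
                raise SchemaError(f"{path}:{rownum}: non-finite energy")
            records.append(
                EnergyRecord(
                    role=role,
                    label=row["label"],
                    n_waters=n_waters,
                    energy=energy,
                    source=row.get("source") or str(path),
                )
            )
    return records


def write_energy_table(records: list[EnergyRecord], path: str | Path) -> None:
    """Write species energies to CSV at full precision (inverse of the reader)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ENERGY_TABLE_HEADER)
        for r in records:
            writer.writerow([r.label, r.role.value, r.n_waters, repr(r.energy), r.source])


def write_input_deck(
    geometry: Geometry,
    spec: ProtocolSpec,
    job: str = "opt_freq",
    title: str = "pkadirect generated deck",
) -> str:
    """Render a plain-text input deck for the external QC engine.

    ``job`` is ``opt_freq`` (geometry optimization + harmonic frequencies,
    the true-minimum workflow) or ``single_point``.
    """
    if len(geometry) == 0:
        raise ConfigError("cannot write a deck for an empty geometry")
    if job not in ("opt_freq", "single_point"):
        raise ConfigError(f"job must be 'opt_freq' or 'single_point', got {job!r}")
    tokens = [f"#p {spec.functional}/{spec.basis}"]
    if job == "opt_freq":
        tokens.append("opt freq")
    if spec.solvation != "none":
        tokens.append(f"scrf=({spec.solvation.lower()},solvent={spec.solvent})")
    lines = [" ".join(tokens), "", title, "", f"{spec.charge} {spec.multiplicity}"]
    for el, (x, y, z) in zip(geometry.elements, geometry.coords):
        lines.append(f"{el:<2s} {x:14.6f} {y:14.6f} {z:14.6f}")
    lines.append("")
    return "\n".join(lines)


def assemble_system(
    calcs: Mapping[Role | str, ParsedCalculation],
    n: int,
    labels: Mapping[Role | str, str] | None = None,
    n_waters: Mapping[Role | str, int] | None = None,
    freq_tol: float = 0.0,
) -> DissociationSystem:
    """Build the four-species system from parsed calculations.

    Species whose frequency block shows an imaginary mode (validate_minimum
    False) are refused with :class:`ProtocolViolationError`; logs without
    frequencies pass (single points carry no claim either way). A species
    parsed with a different explicit-water count than ``n`` raises
    :class:`StoichiometryError`.
    """
    normalized = {Role(k): v for k, v in calcs.items()}
    missing = [r.value for r in Role if r not in normalized]
    if missing:
        raise StoichiometryError(f"missing species for roles {missing}")
    labels = {Role(k): v for k, v in (labels or {}).items()}
    counts = {Role(k): v for k, v in (n_waters or {}).items()}
    records: dict[Role, EnergyRecord] = {}
    for role, calc in normalized.items():
        if validate_minimum(calc, tol=freq_tol) is False:
            raise ProtocolViolationError(
                f"species {role.value} ({calc.source}) has an imaginary frequency; "
                "not a true minimum"
            )
        if calc.final_energy is None:
            raise ParseError(f"species {role.value} ({calc.source}) has no final energy")
        records[role] = EnergyRecord(
            role=role,
            label=labels.get(role, role.value),
            n_waters=counts.get(role, n),
            energy=calc.final_energy,
            source=calc.source,
        )
    return DissociationSystem(
        ha=records[Role.HA],
        a_minus=records[Role.A_MINUS],
        oh_minus=records[Role.OH_MINUS],
        water=records[Role.WATER],
        n=n,
    )


def system_from_records(records: list[EnergyRecord], n: int | None = None) -> DissociationSystem:
    """Build a system from energy-table records (exactly one per role)."""
    by_role: dict[Role, EnergyRecord] = {}
    for r in records:
        if r.role in by_role:
            raise StoichiometryError(f"duplicate role {r.role.value} in energy table")
        by_role[r.role] = r
    missing = [r.value for r in Role if r not in by_role]
    if missing:
        raise StoichiometryError(f"energy table missing roles {missing}")
    if n is None:
        n = by_role[Role.HA].n_waters
    return DissociationSystem(
        ha=by_role[Role.HA],
        a_minus=by_role[Role.A_MINUS],
        oh_minus=by_role[Role.OH_MINUS],
        water=by_role[Role.WATER],
        n=n,
    )
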