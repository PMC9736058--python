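"""Molecular geometries and XYZ exchange.

A :class:`Geometry` is a flat list of element symbols plus Cartesian
coordinates in Angstrom, with optional tags marking the phenolic oxygen and
hydrogen (the reaction center the microsolvation rules build around) and
optional bookkeeping of which atom triples are explicit waters appended by
the placement routine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import InvalidValueError, SchemaError, TaggingError

__all__ = ["Geometry", "read_xyz", "write_xyz", "ATOMIC_NUMBERS", "ELEMENT_SYMBOLS"]

ATOMIC_NUMBERS: dict[str, int] = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Br": 35, "I": 53,
}
ELEMENT_SYMBOLS: dict[int, str] = {z: s for s, z in ATOMIC_NUMBERS.items()}

#: covalent O-H tagging limit, Angstrom
OH_BOND_MAX = 1.2


@dataclass(frozen=True)
class Geometry:
    """Element symbols and Cartesian coordinates (Angstrom).

    ``phenolic_o`` / ``phenolic_h`` are atom indices tagging the reaction
    center; ``water_groups`` lists (O, H, H) index triples for explicit
    waters appended by the placement rules, in placement order.
    """

    elements: tuple[str, ...]
    coords: np.ndarray  # (n, 3) float64, Angstrom
    phenolic_o: int | None = None
    phenolic_h: int | None = None
    water_groups: tuple[tuple[int, int, int], ...] = ()
    comment: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise InvalidValueError(f"coords must be (n, 3), got shape {coords.shape}")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "elements", tuple(self.elements))
        if len(self.elements) != len(coords):
            raise InvalidValueError(
                f"{len(self.elements)} elements vs {len(coords)} coordinate rows"
            )
        if not np.all(np.isfinite(coords)):
            raise InvalidValueError("coordinates must be finite")
        for name in ("phenolic_o", "phenolic_h"):
            idx = getattr(self, name)
            if idx is not None and not (0 <= idx < len(self.elements)):
                raise InvalidValueError(f"{name}={idx} out of range")
        if self.phenolic_o is not None and self.phenolic_h is not None:
            d = float(np.linalg.norm(coords[self.phenolic_o] - coords[self.phenolic_h]))
            if d >= OH_BOND_MAX:
                raise TaggingError(
                    f"tagged phenolic O and H are {d:.3f} A apart (not bonded, "
                    f"limit {OH_BOND_MAX} A)"
                )

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def is_tagged(self) -> bool:
        return self.phenolic_o is not None and self.phenolic_h is not None

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.coords[i] - self.coords[j]))

    def composition(self) -> dict[str, int]:
        """Elemental composition as a symbol -> count map."""
        out: dict[str, int] = {}
        for el in self.elements:
            out[el] = out.get(el, 0) + 1
        return out

    def with_atoms(
        self,
        elements: list[str],
        coords: np.ndarray,
        as_water_group: bool = False,
    ) -> "Geometry":
        """Append atoms; original coordinates are untouched (bit-identical)."""
        new_coords = np.vstack([self.coords, np.asarray(coords, dtype=float)])
        start = len(self.elements)
        groups = self.water_groups
        if as_water_group:
            if len(elements) != 3:
                raise InvalidValueError("a water group must contain exactly 3 atoms")
            groups = groups + ((start, start + 1, start + 2),)
        return replace(
            self,
            elements=self.elements + tuple(elements),
            coords=new_coords,
            water_groups=groups,
        )

    def without_atom(self, index: int) -> "Geometry":
        """Remove one atom, remapping tags and water groups."""
        if not (0 <= index < len(self)):
            raise InvalidValueError(f"atom index {index} out of range")

        def remap(i: int | None) -> int | None:
            if i is None or i == index:
                return None
            return i - 1 if i > index else i

        groups = []
        for g in self.water_groups:
            if index in g:
                continue
            groups.append(tuple(remap(i) for i in g))
        keep = [i for i in range(len(self)) if i != index]
        return replace(
            self,
            elements=tuple(self.elements[i] for i in keep),
            coords=self.coords[keep],
            phenolic_o=remap(self.phenolic_o),
            phenolic_h=remap(self.phenolic_h),
            water_groups=tuple(groups),
        )


def read_xyz(path: str | Path) -> Geometry:
    """Read a standard XYZ file (count, comment, element x y z per line)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise SchemaError(f"{path}: empty XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise SchemaError(f"{path}: first line must be the atom count") from exc
    if len(lines) < n + 2:
        raise SchemaError(f"{path}: expected {n} atom lines, found {len(lines) - 2}")
    comment = lines[1] if len(lines) > 1 else ""
    elements: list[str] = []
    coords: list[list[float]] = []
    for k, line in enumerate(lines[2 : 2 + n], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise SchemaError(f"{path}:{k}: expected 'element x y z'")
        elements.append(parts[0])
        try:
            coords.append([float(v) for v in parts[1:4]])
        except ValueError as exc:
            raise SchemaError(f"{path}:{k}: non-numeric coordinate") from exc
    return Geometry(elements=tuple(elements), coords=np.array(coords), comment=comment)


def write_xyz(g: Geometry, path: str | Path) -> None:
    """Write a standard XYZ file with 6-decimal coordinates."""
    lines = [str(len(g)), g.comment]
    for el, (x, y, z) in zip(g.elements, g.coords):
        lines.append(f"{el:<2s} {x:14.6f} {y:14.6f} {z:14.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < 1e-12:
        raise InvalidValueError("cannot normalize a zero vector")
    return v / n


def any_perpendicular(v: np.ndarray) -> np.ndarray:
    """A deterministic unit vector perpendicular to v."""
    v = unit(v)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(float(np.dot(v, ref))) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    return unit(np.cross(v, ref))


def rotate_about(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis by angle (radians)."""
    axis = unit(axis)
    return (
        v * math.cos(angle)
        + np.cross(axis, v) * math.sin(angle)
        + axis * float(np.dot(axis, v)) * (1.0 - math.cos(angle))
    )
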