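"""Explicit-water starting geometries around a phenolic OH group.

The first-solvation-shell protocol attaches zero, one or two water
molecules to each species of the hydroxide-exchange reaction before the QC
engine relaxes them. Published workflows build these starting structures by
hand ("chemical intuition"); here the construction is deterministic and
rule-based so it is reproducible:

* water 1 accepts a hydrogen bond from the phenolic H — its oxygen is
  placed on the O-H axis at a chosen H...O distance (default 1.9 A), with
  its own hydrogens pointing away from the solute;
* water 2 donates a hydrogen bond to the phenolic oxygen's in-plane lone
  pair — its donating H sits at the chosen H...O distance along the
  direction bisecting the reflex C-O-H angle.

The construction window (1.5-2.5 A) brackets the H-bond lengths that
relaxed closed-cage phenol structures exhibit (roughly 1.77-2.14 A), so the
starting points are realistic seeds for optimization.

A two-water arrangement is a *closed* cage when both waters hydrogen-bond
to the OH group; it is *open* when the second water sits more than 4 A from
the OH group (electron-withdrawing substituents such as nitro and cyano
favor this by draining the oxygen lone pair). Both topologies can be
constructed; classification uses the strict >4 A criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import (
    ClassificationError,
    InvalidValueError,
    PlacementError,
    TaggingError,
)
from .geometry import Geometry, any_perpendicular, rotate_about, unit

__all__ = [
    "CageReport",
    "AtomBalanceReport",
    "auto_tag_phenolic",
    "place_waters",
    "hbond_lengths",
    "classify_cage",
    "check_atom_balance",
]

# water internal geometry, Angstrom / degrees (gas-phase experimental values)
WATER_OH = 0.9572
WATER_ANGLE = math.radians(104.52)

#: default donor-H...acceptor distance for placed waters, Angstrom
DEFAULT_HBOND = 1.9

#: minimum allowed non-bonded contact, Angstrom
CLASH_LIMIT = 1.5

#: open-cage threshold: second water farther than this from the OH group, Angstrom
OPEN_CAGE_THRESHOLD = 4.0

_COVALENT_OH = 1.2
_COVALENT_CO = 1.6
_HBOND_CUTOFF = 2.5


@dataclass(frozen=True)
class CageReport:
    """Hydrogen-bond cage classification of a two-water arrangement."""

    hbond_lengths: tuple[float, ...]
    classification: str  # "closed" | "open"
    second_water_OH_distance: float | None = None


@dataclass(frozen=True)
class AtomBalanceReport:
    """Elemental balance of the four reaction species; diff is LHS - RHS."""

    balanced: bool
    diff: dict[str, int]

    def __bool__(self) -> bool:
        return self.balanced


def auto_tag_phenolic(g: Geometry) -> Geometry:
    """Tag the phenolic O and H: the O bonded to a carbon with exactly one H.

    Raises :class:`TaggingError` when no unique candidate exists; manual
    tagging via the Geometry fields overrides this.
    """
    if g.is_tagged:
        return g
    candidates: list[tuple[int, int]] = []
    for i, el in enumerate(g.elements):
        if el != "O":
            continue
        h_nb = [
            j
            for j, e2 in enumerate(g.elements)
            if e2 == "H" and j != i and g.distance(i, j) < _COVALENT_OH
        ]
        c_nb = [
            j
            for j, e2 in enumerate(g.elements)
            if e2 == "C" and g.distance(i, j) < _COVALENT_CO
        ]
        if len(h_nb) == 1 and c_nb:
            candidates.append((i, h_nb[0]))
    if not candidates:
        raise TaggingError("no phenolic O-H (oxygen bonded to C with exactly one H) found")
    if len(candidates) > 1:
        raise TaggingError(
            f"ambiguous phenolic O-H: candidates at O indices "
            f"{[c[0] for c in candidates]}; tag manually"
        )
    o_idx, h_idx = candidates[0]
    return Geometry(
        elements=g.elements,
        coords=g.coords,
        phenolic_o=o_idx,
        phenolic_h=h_idx,
        water_groups=g.water_groups,
        comment=g.comment,
    )


def _water_atoms(o_pos: np.ndarray, bisector: np.ndarray, in_plane: np.ndarray):
    """Water (O, H, H) coordinates: bisector points from O between the two H."""
    b = unit(bisector)
    p = unit(in_plane - b * float(np.dot(in_plane, b)))
    half = WATER_ANGLE / 2.0
    h1 = o_pos + WATER_OH * (math.cos(half) * b + math.sin(half) * p)
    h2 = o_pos + WATER_OH * (math.cos(half) * b - math.sin(half) * p)
    return np.array([o_pos, h1, h2])


def _lone_pair_direction(g: Geometry) -> np.ndarray:
    """In-plane lone-pair direction of the tagged O: away from all its
    covalent neighbors (for phenol, the bisector of the reflex C-O-H angle)."""
    o = g.coords[g.phenolic_o]
    acc = np.zeros(3)
    for j, el in enumerate(g.elements):
        if j == g.phenolic_o:
            continue
        limit = _COVALENT_OH if el == "H" else _COVALENT_CO
        if g.distance(g.phenolic_o, j) < limit:
            acc += unit(g.coords[j] - o)
    if float(np.linalg.norm(acc)) < 1e-9:
        raise TaggingError("tagged O has no covalent neighbors; cannot orient lone pair")
    return -unit(acc)


def _clashes(g: Geometry, new_start: int) -> bool:
    """True if any appended atom sits closer than CLASH_LIMIT to an atom
    outside its own water molecule."""
    groups = {i: gi for gi, grp in enumerate(g.water_groups) for i in grp}
    for i in range(new_start, len(g)):
        for j in range(len(g)):
            if j >= new_start and groups.get(j) == groups.get(i):
                continue
            if j == i:
                continue
            if g.distance(i, j) < CLASH_LIMIT:
                return True
    return False


def place_waters(
    g: Geometry,
    n: int,
    d1: float = DEFAULT_HBOND,
    d2: float = DEFAULT_HBOND,
    open_cage: bool = False,
    open_distance: float = 4.5,
) -> Geometry:
    """Attach n explicit waters (0, 1 or 2) to the tagged phenolic OH.

    Original atoms are never moved. ``open_cage=True`` (n=2 only) parks the
    second water beyond the open-cage threshold instead of donating to the
    oxygen lone pair. Raises :class:`PlacementError` if the deterministic
    staggering rule cannot resolve a steric clash.
    """
    if n not in (0, 1, 2):
        raise InvalidValueError(f"n must be 0, 1 or 2, got {n}")
    if n == 0:
        return g
    if not g.is_tagged:
        raise TaggingError("geometry must carry phenolic O/H tags; see auto_tag_phenolic")
    for name, d in (("d1", d1), ("d2", d2)):
        if not (1.5 < d < 2.5):
            raise InvalidValueError(f"{name} must lie in (1.5, 2.5) A, got {d}")

    o = g.coords[g.phenolic_o]
    h = g.coords[g.phenolic_h]
    u = unit(h - o)  # O->H direction of the phenolic bond
    perp = any_perpendicular(u)

    # water 1: acceptor on the O-H axis, hydrogens pointing away
    w1_o = h + d1 * u
    out = None
    for angle in (0.0, math.pi / 2, math.pi, 3 * math.pi / 2):
        p = rotate_about(perp, u, angle)
        cand = g.with_atoms(["O", "H", "H"], _water_atoms(w1_o, u, p), as_water_group=True)
        if not _clashes(cand, len(g)):
            out = cand
            break
    if out is None:
        raise PlacementError("first water clashes with the solute in every stagger")
    if n == 1:
        return out

    lp = _lone_pair_direction(g)
    if open_cage:
        w2_o = o + (open_distance + WATER_OH) * lp
        bis = lp
    else:
        # water 2 donates: its H at d2 from the phenolic O along the lone pair
        w2_h = o + d2 * lp
        w2_o = w2_h + WATER_OH * lp
        bis = -lp  # bisector points back toward the donated H side
    base = out
    out2 = None
    normal = unit(np.cross(u, lp)) if abs(float(np.dot(u, lp))) < 0.999 else perp
    for p in (normal, -normal, rotate_about(normal, lp, math.pi / 2)):
        if open_cage:
            atoms = _water_atoms(w2_o, bis, p)
        else:
            # donating H must stay exactly on the lone-pair axis: build the
            # water with one O-H bond along -lp and the other staggered
            hd = w2_o - WATER_OH * lp
            other_dir = rotate_about(-lp, p, WATER_ANGLE)
            h2 = w2_o + WATER_OH * other_dir
            atoms = np.array([w2_o, hd, h2])
        cand = base.with_atoms(["O", "H", "H"], atoms, as_water_group=True)
        if not _clashes(cand, len(base)):
            out2 = cand
            break
    if out2 is None:
        raise PlacementError("second water clashes with the cluster in every stagger")
    return out2


def _covalent_partners(g: Geometry, h_idx: int) -> list[int]:
    return [
        j
        for j, el in enumerate(g.elements)
        if el in ("O", "N") and g.distance(h_idx, j) < _COVALENT_OH
    ]


def hbond_lengths(g: Geometry, cutoff: float = _HBOND_CUTOFF) -> list[float]:
    """All donor-H...acceptor distances below ``cutoff``, sorted ascending.

    Donors are O/N-bound hydrogens; acceptors are O/N atoms other than the
    hydrogen's own covalent partner.
    """
    out: list[float] = []
    for i, el in enumerate(g.elements):
        if el != "H":
            continue
        partners = _covalent_partners(g, i)
        if not partners:
            continue
        for j, el2 in enumerate(g.elements):
            if el2 not in ("O", "N") or j in partners:
                continue
            d = g.distance(i, j)
            if _COVALENT_OH <= d < cutoff:
                out.append(d)
    return sorted(out)


def classify_cage(g: Geometry, threshold: float = OPEN_CAGE_THRESHOLD) -> CageReport:
    """Open/closed classification of a two-water hydration cage.

    The cage is *open* iff the second placed water's oxygen lies strictly
    more than ``threshold`` from the OH group (nearer of phenolic O and H);
    the boundary value itself is closed.
    """
    if len(g.water_groups) < 2:
        raise ClassificationError(
            f"cage classification needs >= 2 identified waters, found {len(g.water_groups)}"
        )
    if not g.is_tagged:
        raise TaggingError("geometry must carry phenolic O/H tags")
    w2_o = g.water_groups[1][0]
    d = min(g.distance(w2_o, g.phenolic_o), g.distance(w2_o, g.phenolic_h))
    cls = "open" if d > threshold else "closed"
    return CageReport(
        hbond_lengths=tuple(hbond_lengths(g)),
        classification=cls,
        second_water_OH_distance=d,
    )


def check_atom_balance(
    ha: Geometry, a_minus: Geometry, oh_minus: Geometry, water: Geometry
) -> AtomBalanceReport:
    """Elemental conservation of HA + OH- vs A- + H2O (each with its waters).

    Never raises: an unbalanced system returns ``balanced=False`` with a
    per-element difference (left minus right).
    """
    lhs: dict[str, int] = {}
    rhs: dict[str, int] = {}
    for geom, acc in ((ha, lhs), (oh_minus, lhs), (a_minus, rhs), (water, rhs)):
        for el, cnt in geom.composition().items():
            acc[el] = acc.get(el, 0) + cnt
    diff = {
        el: lhs.get(el, 0) - rhs.get(el, 0)
        for el in sorted(set(lhs) | set(rhs))
        if lhs.get(el, 0) != rhs.get(el, 0)
    }
    return AtomBalanceReport(balanced=not diff, diff=diff)


def deprotonate(g: Geometry) -> Geometry:
    """Phenolate geometry: the tagged HA minus its phenolic H, waters kept."""
    if g.phenolic_h is None:
        raise TaggingError("cannot deprotonate: phenolic H not tagged")
    return g.without_atom(g.phenolic_h)
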