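"""Ligand hydrogen placement, aromatic-ring perception, X-H...pi contacts
and the ligand hydrogen-bond network.

The central operation is the P-H...pi criterion: a phosphorus-bonded
hydrogen lying within the sum of van der Waals radii of an aromatic ring
plane (H + aromatic C = 2.9 A, Bondi), over the ring face (small centroid
offset), with a wide donor-H-centroid angle. Crystallographic models do not
include P-H hydrogens, so they are placed geometrically first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from ._radii import vdw_radius
from .geometry import PlaneFit, fit_plane
from .structure_io import AtomRecord, LigandInstance, Structure

__all__ = [
    "PiCriteria",
    "AromaticRing",
    "PiContact",
    "HBond",
    "InteractionError",
    "place_ligand_hydrogens",
    "find_aromatic_rings",
    "detect_pi_contacts",
    "detect_hbonds",
    "P_H_BOND_LENGTH",
    "RING_DEFINITIONS",
]

#: P-H bond length in Angstroms (standard phosphine/phosphonate value).
P_H_BOND_LENGTH = 1.42

TETRAHEDRAL_ANGLE = math.degrees(math.acos(-1.0 / 3.0))  # 109.471...

#: Canonical ring-atom names per residue type. TRP contributes two rings.
RING_DEFINITIONS: dict[str, list[tuple[str, tuple[str, ...]]]] = {
    "PHE": [("PHE6", ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"))],
    "TYR": [("TYR6", ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"))],
    "TRP": [
        ("TRP5", ("CG", "CD1", "CD2", "NE1", "CE2")),
        ("TRP6", ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")),
    ],
    "HIS": [("HIS5", ("CG", "ND1", "CD2", "CE1", "NE2"))],
}

PLANARITY_GATE = 0.1  # A rms; rings failing it are reported, not used


class InteractionError(ValueError):
    """Raised for unsupported ligand chemistry or missing preconditions."""


@dataclass
class PiCriteria:
    """Acceptance window for an X-H...pi contact.

    ``max_plane_distance`` defaults to 2.9 A = r_vdW(H) + r_vdW(C), the Bondi
    sum for hydrogen over an aromatic carbon; the angle is the
    donor-H-centroid angle at the hydrogen.
    """

    max_plane_distance: float = vdw_radius("H") + vdw_radius("C")  # 2.9
    max_centroid_offset: float = 1.6
    angle_range: tuple[float, float] = (120.0, 180.0)
    donor_elements: frozenset[str] = frozenset({"P", "C", "N", "O", "S"})

    def __post_init__(self) -> None:
        if self.max_plane_distance <= 0:
            raise InteractionError("max_plane_distance must be positive")
        lo, hi = self.angle_range
        if not (0.0 <= lo <= hi <= 180.0):
            raise InteractionError("angle_range must lie within [0,180]")


@dataclass
class AromaticRing:
    """A planar aromatic ring with its fitted plane."""

    chain_id: str
    residue_number: int
    residue_name: str
    ring_label: str
    atoms: list[AtomRecord]
    plane: PlaneFit

    @property
    def residue_id(self) -> str:
        return f"{self.residue_name}{self.residue_number}({self.chain_id})"


@dataclass
class PiContact:
    """A detected X-H...pi contact and its geometry."""

    donor_atom: AtomRecord
    hydrogen: np.ndarray
    ring: AromaticRing
    plane_distance: float
    centroid_offset: float
    approach_angle: float

    @property
    def ring_residue(self) -> str:
        return self.ring.residue_id


@dataclass
class HBond:
    """A distance-criterion hydrogen bond between a ligand oxygen and a
    protein/water N or O partner (heavy-atom distance only: the models carry
    no protein hydrogens, so no D-H-A angle can be applied)."""

    donor: AtomRecord
    acceptor: AtomRecord
    distance: float

    @property
    def partner_residue(self) -> str:
        p = self.acceptor
        return f"{p.residue_name}{p.residue_number}({p.chain_id})"


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise InteractionError("zero-length vector in hydrogen construction")
    return v / n


def place_ligand_hydrogens(lig: LigandInstance) -> LigandInstance:
    """Model the P-bonded hydrogens of a phosphorus oxyanion ligand.

    Phosphite (1 P, 3 O): a single hydrogen completes the tetrahedron, along
    the negated, normalised sum of the P->O unit vectors. Hypophosphite
    (1 P, 2 O): two hydrogens in the plane through P spanned by the negated
    O-P-O bisector and the O-P-O normal, separated by the tetrahedral angle.
    Methylphosphonate (3 O + 1 C) carries no P-H and gets none. The hydroxyl
    proton of mono-anionic phosphite is never placed; only P-H hydrogens
    enter the pi criterion.
    """
    p = lig.phosphorus.coords
    n_o, n_c = len(lig.oxygens), len(lig.carbons)
    if n_o == 3 and n_c == 1:
        return replace(lig, hydrogens=[])  # methylphosphonate: no P-H
    if n_c != 0 or n_o not in (2, 3):
        raise InteractionError(
            f"unsupported substituent pattern: {n_o} O, {n_c} C around P "
            "(expected 3 O = phosphite, 2 O = hypophosphite, 3 O + 1 C = MPn)"
        )
    units = [_unit(o.coords - p) for o in lig.oxygens]
    if n_o == 3:
        s = np.sum(units, axis=0)
        h_dir = -_unit(s)
        hydrogens = [p + P_H_BOND_LENGTH * h_dir]
    else:
        u1, u2 = units
        bisector = _unit(u1 + u2)
        normal = _unit(np.cross(u1, u2))
        half = math.radians(TETRAHEDRAL_ANGLE / 2.0)
        d1 = -bisector * math.cos(half) + normal * math.sin(half)
        d2 = -bisector * math.cos(half) - normal * math.sin(half)
        hydrogens = [p + P_H_BOND_LENGTH * d1, p + P_H_BOND_LENGTH * d2]
    return replace(lig, hydrogens=hydrogens)


def find_aromatic_rings(
    s: Structure,
    near: np.ndarray | None = None,
    radius: float = 8.0,
) -> tuple[list[AromaticRing], list[str]]:
    """Perceive aromatic rings by canonical residue/atom names.

    Returns ``(rings, skipped)`` where ``skipped`` reports rings with missing
    member atoms or planarity RMS above 0.1 A. With ``near`` set, only rings
    whose centroid lies within ``radius`` of that point are returned.
    """
    residues: dict[tuple[str, int, str], dict[str, AtomRecord]] = {}
    for a in s.atoms:
        if a.residue_name in RING_DEFINITIONS and not a.is_hetero:
            residues.setdefault(a.residue_key(), {})[a.name] = a

    rings: list[AromaticRing] = []
    skipped: list[str] = []
    for (chain, number, resname), atom_map in sorted(residues.items()):
        for label, names in RING_DEFINITIONS[resname]:
            members = [atom_map.get(n) for n in names]
            tag = f"{resname}{number}({chain})/{label}"
            if any(m is None for m in members):
                missing = [n for n, m in zip(names, members) if m is None]
                skipped.append(f"{tag}: missing atoms {','.join(missing)}")
                continue
            plane = fit_plane([m.coords for m in members])
            if plane.planarity_rms >= PLANARITY_GATE:
                skipped.append(
                    f"{tag}: planarity rms {plane.planarity_rms:.3f} A >= {PLANARITY_GATE}"
                )
                continue
            if near is not None and np.linalg.norm(plane.centroid - np.asarray(near, float)) > radius:
                continue
            rings.append(
                AromaticRing(
                    chain_id=chain,
                    residue_number=number,
                    residue_name=resname,
                    ring_label=label,
                    atoms=list(members),
                    plane=plane,
                )
            )
    return rings, skipped


def detect_pi_contacts(
    lig: LigandInstance,
    rings: list[AromaticRing],
    criteria: PiCriteria | None = None,
) -> list[PiContact]:
    """Score every (placed hydrogen, ring) pair against the pi criterion.

    For each pair: ``d`` is the unsigned perpendicular distance from H to the
    ring plane, the centroid offset is the in-plane distance of H's
    projection from the ring centroid, and the approach angle is measured at
    H between the H->donor and H->centroid directions. A contact is emitted
    iff all three lie inside the criteria window; results are sorted by
    ascending ``d``.
    """
    if criteria is None:
        criteria = PiCriteria()
    if not lig.hydrogens:
        raise InteractionError(
            "ligand has no placed hydrogens; run place_ligand_hydrogens first "
            "(methylphosphonate carries no P-H and can yield no P-H...pi contact)"
        )
    donor = lig.phosphorus
    if donor.element not in criteria.donor_elements:
        return []
    contacts: list[PiContact] = []
    for h in lig.hydrogens:
        h = np.asarray(h, float)
        for ring in rings:
            d = abs(ring.plane.signed_distance(h))
            if d > criteria.max_plane_distance:
                continue
            offset = float(np.linalg.norm(ring.plane.project(h) - ring.plane.centroid))
            if offset > criteria.max_centroid_offset:
                continue
            to_donor = donor.coords - h
            to_centroid = ring.plane.centroid - h
            cosang = np.dot(to_donor, to_centroid) / (
                np.linalg.norm(to_donor) * np.linalg.norm(to_centroid)
            )
            theta = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            lo, hi = criteria.angle_range
            if not (lo <= theta <= hi):
                continue
            contacts.append(
                PiContact(
                    donor_atom=donor,
                    hydrogen=h,
                    ring=ring,
                    plane_distance=d,
                    centroid_offset=offset,
                    approach_angle=theta,
                )
            )
    contacts.sort(key=lambda c: c.plane_distance)
    return contacts


def detect_hbonds(
    lig: LigandInstance,
    s: Structure,
    cutoff: float = 3.5,
    include_waters: bool = True,
) -> list[HBond]:
    """Hydrogen bonds from ligand oxygens to protein N/O (and water O).

    Distance-only criterion on heavy atoms; carbon partners and atoms of the
    ligand residue itself are excluded; duplicate pairs are not emitted.
    """
    if not lig.oxygens:
        return []
    lig_key = lig.phosphorus.residue_key()
    bonds: list[HBond] = []
    seen: set[tuple[str, tuple[str, int, str], str, tuple[str, int, str]]] = set()
    for o in lig.oxygens:
        for a in s.atoms:
            if a.element not in ("N", "O"):
                continue
            if a.residue_key() == lig_key:
                continue
            if a.is_water and not include_waters:
                continue
            if a.is_hetero and not a.is_water:
                continue  # other hetero ligands are not H-bond partners here
            dist = float(np.linalg.norm(a.coords - o.coords))
            if dist > cutoff:
                continue
            key = (o.name, o.residue_key(), a.name, a.residue_key())
            if key in seen:
                continue
            seen.add(key)
            bonds.append(HBond(donor=o, acceptor=a, distance=dist))
    bonds.sort(key=lambda b: b.distance)
    return bonds
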