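"""Coordinate-file input and atom selection.

Reads PDB and mmCIF files into a flat, uniform atom model (via gemmi), with
the conventions used throughout the package: only the first model, one altloc
conformer per atom, author residue numbering as the sole addressing scheme,
waters retained but flagged, deuterium treated as hydrogen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "LigandInstance",
    "StructureError",
    "AmbiguousSelectionError",
    "read_structure",
    "write_structure",
    "extract_ligand",
    "select_calpha",
]

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

# Two-letter element symbols used to disambiguate atom-name prefixes when the
# element column is absent (e.g. "CA" calcium vs C-alpha carbon is resolved by
# the PDB column convention handled below).
_TWO_LETTER_ELEMENTS = frozenset(
    {
        "HE", "LI", "BE", "NE", "NA", "MG", "AL", "SI", "CL", "AR", "CA",
        "SC", "TI", "CR", "MN", "FE", "CO", "NI", "CU", "ZN", "GA", "GE",
        "AS", "SE", "BR", "KR", "RB", "SR", "MO", "RU", "RH", "PD", "AG",
        "CD", "SN", "SB", "TE", "XE", "CS", "BA", "PT", "AU", "HG", "TL",
        "PB",
    }
)


class StructureError(ValueError):
    """Raised for unreadable, empty, or inconsistent coordinate input."""


class AmbiguousSelectionError(StructureError):
    """Raised when a ligand selector matches zero or multiple residues."""

    def __init__(self, message: str, candidates: list[str] | None = None):
        super().__init__(message)
        self.candidates = candidates or []


@dataclass
class AtomRecord:
    """One atom: name, element, coordinates and residue addressing.

    Residue numbers follow author numbering, which is how binding-site
    residues (e.g. the capping tyrosine Y208 in Te_PtxB) are referred to.
    """

    name: str
    element: str
    coords: np.ndarray
    residue_name: str
    residue_number: int
    chain_id: str
    altloc: str = ""
    occupancy: float = 1.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: coords must be a finite 3-vector")
        if not (0.0 <= self.occupancy <= 1.0):
            raise StructureError(f"atom {self.name}: occupancy {self.occupancy} outside [0,1]")
        if not self.element:
            raise StructureError(f"atom {self.name}: empty element after inference")

    @property
    def is_water(self) -> bool:
        return self.residue_name in WATER_NAMES

    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.residue_name)


@dataclass
class Structure:
    """An ordered list of atoms from one model of one coordinate file."""

    atoms: list[AtomRecord]
    id: str = ""
    model_number: int = 1

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def protein_heavy_atoms(self, include_waters: bool = False) -> list[AtomRecord]:
        """Non-hydrogen atoms excluding hetero ligands; waters optional."""
        out = []
        for a in self.atoms:
            if a.element in ("H", "D"):
                continue
            if a.is_water:
                if include_waters:
                    out.append(a)
                continue
            if a.is_hetero:
                continue
            out.append(a)
        return out


@dataclass
class LigandInstance:
    """A phosphorus oxyanion ligand (phosphite, hypophosphite, MPn, ...).

    Atoms are partitioned by element; ``hydrogens`` holds P-bonded hydrogen
    positions which are absent from crystallographic models and must be
    placed by :func:`phosbind.interactions.place_ligand_hydrogens`.
    """

    residue_name: str
    atoms: list[AtomRecord]
    phosphorus: AtomRecord
    oxygens: list[AtomRecord]
    carbons: list[AtomRecord]
    hydrogens: list[np.ndarray] = field(default_factory=list)

    @property
    def chain_id(self) -> str:
        return self.phosphorus.chain_id

    @property
    def residue_number(self) -> int:
        return self.phosphorus.residue_number

    def centroid(self) -> np.ndarray:
        return np.mean([a.coords for a in self.atoms], axis=0)


def _infer_element(atom_name: str, residue_is_hetero: bool) -> str:
    """Infer the element from an atom name when the element column is absent."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise StructureError(f"cannot infer element from atom name {atom_name!r}")
    two = stripped[:2].upper()
    if len(stripped) >= 2 and two in _TWO_LETTER_ELEMENTS and residue_is_hetero:
        return two[0] + two[1].lower()
    one = stripped[0].upper()
    if one == "D":
        return "H"
    return one


def _from_gemmi(st: gemmi.Structure, structure_id: str) -> Structure:
    if len(st) == 0:
        raise StructureError(f"{structure_id}: no models in file")
    model = st[0]
    atoms: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            het = residue.het_flag == "H"
            for atom in residue:
                alt = atom.altloc if atom.altloc != "\x00" else ""
                if alt not in ("", "A"):
                    continue  # keep the A (or blank) conformer only
                if atom.element.name and atom.element.name != "X":
                    element = atom.element.name
                else:
                    element = _infer_element(atom.name, het)
                if element == "D":
                    element = "H"
                atoms.append(
                    AtomRecord(
                        name=atom.name,
                        element=element,
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        residue_name=residue.name,
                        residue_number=residue.seqid.num,
                        chain_id=chain.name,
                        altloc=alt,
                        occupancy=min(max(atom.occ, 0.0), 1.0),
                        is_hetero=het or residue.name in WATER_NAMES,
                    )
                )
    if not atoms:
        raise StructureError(f"{structure_id}: zero atoms after filtering")
    return Structure(atoms=atoms, id=structure_id, model_number=int(model.num))


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF coordinate file.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"pdb"``, ``"mmcif"`` or ``"auto"`` (dispatch on extension, then on
        content).

    Returns the first model only, with altlocs other than ''/'A' dropped.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    fmt = format.lower()
    if fmt == "auto":
        suffix = path.suffix.lower()
        if suffix in (".cif", ".mmcif"):
            fmt = "mmcif"
        elif suffix in (".pdb", ".ent"):
            fmt = "pdb"
        else:
            head = path.read_text(errors="replace")[:2048]
            fmt = "mmcif" if head.lstrip().startswith("data_") or "_atom_site" in head else "pdb"
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise StructureError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"failed to parse {path} as {fmt}: {exc}") from exc
    st.setup_entities()
    return _from_gemmi(st, structure_id=path.stem)


def _to_gemmi(s: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = s.id or "phosbind"
    model = gemmi.Model(1)
    chain_map: dict[str, gemmi.Chain] = {}
    for a in s.atoms:
        chain = chain_map.get(a.chain_id)
        if chain is None:
            chain = gemmi.Chain(a.chain_id or "A")
            chain_map[a.chain_id] = chain
        if len(chain) == 0 or chain[-1].seqid.num != a.residue_number or chain[-1].name != a.residue_name:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, " ")
            res.het_flag = "H" if a.is_hetero else "A"
            chain.add_residue(res)
        res = chain[-1]
        atom = gemmi.Atom()
        atom.name = a.name
        atom.element = gemmi.Element(a.element)
        atom.pos = gemmi.Position(*a.coords)
        atom.occ = a.occupancy
        atom.altloc = a.altloc if a.altloc else "\x00"
        res.add_atom(atom)
    for chain in chain_map.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(s: Structure, path: str | Path, format: str = "auto") -> None:
    """Write a structure to PDB (3-decimal coordinates) or mmCIF."""
    path = Path(path)
    fmt = format.lower()
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    st = _to_gemmi(s)
    if fmt == "pdb":
        st.write_pdb(str(path))
    elif fmt == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise StructureError(f"unknown format {format!r}")


def extract_ligand(
    s: Structure,
    residue_name: str,
    chain_id: str | None = None,
    residue_number: int | None = None,
) -> LigandInstance:
    """Select one hetero P-ligand residue and partition its atoms by element.

    The selector must match exactly one residue; with multiple ligand copies
    a chain (and/or residue number) must be given.
    """
    groups: dict[tuple[str, int, str], list[AtomRecord]] = {}
    for a in s.atoms:
        if a.residue_name != residue_name:
            continue
        if chain_id is not None and a.chain_id != chain_id:
            continue
        if residue_number is not None and a.residue_number != residue_number:
            continue
        groups.setdefault(a.residue_key(), []).append(a)
    if not groups:
        raise AmbiguousSelectionError(
            f"no residue named {residue_name!r} matches the selector", candidates=[]
        )
    if len(groups) > 1:
        cands = [f"{k[2]} {k[0]}{k[1]}" for k in sorted(groups)]
        raise AmbiguousSelectionError(
            f"selector {residue_name!r} matches {len(groups)} residues: " + ", ".join(cands),
            candidates=cands,
        )
    atoms = next(iter(groups.values()))
    phosphorus = [a for a in atoms if a.element == "P"]
    if len(phosphorus) != 1:
        raise StructureError(
            f"residue {residue_name} has {len(phosphorus)} phosphorus atoms; "
            "expected exactly 1 (not a supported P ligand)"
        )
    oxygens = [a for a in atoms if a.element == "O"]
    carbons = [a for a in atoms if a.element == "C"]
    return LigandInstance(
        residue_name=residue_name,
        atoms=atoms,
        phosphorus=phosphorus[0],
        oxygens=oxygens,
        carbons=carbons,
    )


def select_calpha(
    s: Structure,
    chain_id: str,
    ranges: Sequence[tuple[int, int]],
) -> tuple[np.ndarray, list[int], list[int]]:
    """Collect one C-alpha per residue over inclusive author-number ranges.

    Returns ``(coords, residue_numbers, skipped)`` where ``skipped`` lists
    residue numbers present in the chain within the ranges but lacking a CA.
    """
    rs = [(int(lo), int(hi)) for lo, hi in ranges]
    for lo, hi in rs:
        if lo > hi:
            raise StructureError(f"range {lo}-{hi} is not ascending")
    for (lo1, hi1), (lo2, hi2) in zip(rs, rs[1:]):
        if hi1 >= lo2:
            raise StructureError("ranges must be non-overlapping and ascending")

    def in_ranges(num: int) -> bool:
        return any(lo <= num <= hi for lo, hi in rs)

    ca: dict[int, np.ndarray] = {}
    residues_seen: set[int] = set()
    for a in s.atoms:
        if a.chain_id != chain_id or a.is_hetero or a.is_water:
            continue
        if not in_ranges(a.residue_number):
            continue
        residues_seen.add(a.residue_number)
        if a.name == "CA" and a.element == "C" and a.residue_number not in ca:
            ca[a.residue_number] = a.coords
    if not ca:
        raise StructureError(
            f"empty C-alpha selection for chain {chain_id!r}, ranges {rs}"
        )
    numbers = sorted(ca)
    skipped = sorted(residues_seen - set(numbers))
    coords = np.array([ca[n] for n in numbers], dtype=float)
    return coords, numbers, skipped
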