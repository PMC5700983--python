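"""Synthetic fixtures with known ground truth.

Every generator is a pure, seeded function of its spec: idealised
aromatic-ring/ligand pi sites built by inverse construction (so the
downstream detector must recover the requested geometry exactly), two-lobe
C-alpha traces with a known closure rotation, watertight pseudo-atom shells
enclosing a spherical cavity, and simulated MST dilution series and ITC
titrations at known binding parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .binding import (
    BindingCurve,
    Eq1Params,
    ItcTitration,
    eq1_model,
    itc_forward,
)
from .interactions import P_H_BOND_LENGTH, TETRAHEDRAL_ANGLE
from .structure_io import AtomRecord, LigandInstance, Structure, extract_ligand

__all__ = [
    "PiSiteSpec",
    "TwoLobeSpec",
    "MstSimSpec",
    "CavityFixture",
    "InfeasibleSpecError",
    "make_pi_site",
    "make_two_lobe",
    "make_cavity",
    "simulate_mst",
    "simulate_itc",
    "PHOSPHITE_RESNAME",
    "HYPOPHOSPHITE_RESNAME",
]

#: Fixture-local hetero codes for the generated ligands (the deposited
#: chemical-component IDs vary between entries, so fixtures use their own).
PHOSPHITE_RESNAME = "PHS"
HYPOPHOSPHITE_RESNAME = "HPS"

P_O_BOND = 1.52  # A, P-O in phosphorus oxyanions
RING_CC = 1.39  # A, aromatic C-C

_TET = math.radians(TETRAHEDRAL_ANGLE)


class InfeasibleSpecError(ValueError):
    """Raised when a requested fixture geometry cannot be realised."""


@dataclass(frozen=True)
class PiSiteSpec:
    """Target geometry of a P-H...pi site: hydrogen at perpendicular
    distance ``plane_distance`` over the ring, in-plane offset
    ``centroid_offset`` from the centroid, donor-H-centroid angle
    ``approach_angle``."""

    plane_distance: float = 2.6
    approach_angle: float = 140.0
    centroid_offset: float = 0.3
    ring_type: str = "TYR6"
    ligand: str = "phosphite"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plane_distance <= 0:
            raise InfeasibleSpecError("plane_distance must be positive")
        if not (90.0 < self.approach_angle <= 180.0):
            raise InfeasibleSpecError("approach_angle must lie in (90, 180]")
        if self.centroid_offset < 0:
            raise InfeasibleSpecError("centroid_offset must be >= 0")
        if self.ring_type not in ("TYR6", "TRP6"):
            raise InfeasibleSpecError("ring_type must be TYR6 or TRP6")
        if self.ligand not in ("phosphite", "hypophosphite"):
            raise InfeasibleSpecError("ligand must be phosphite or hypophosphite")


@dataclass(frozen=True)
class TwoLobeSpec:
    """A two-lobe C-alpha fixture: lobe sizes, the rigid closure rotation
    applied to lobe 1, and the axis it is applied about."""

    n_res_lobe1: int = 60
    n_res_lobe2: int = 60
    closure_angle: float = 60.0
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_res_lobe1 < 20 or self.n_res_lobe2 < 20:
            raise InfeasibleSpecError("each lobe needs >= 20 residues")
        if not (0.0 <= self.closure_angle <= 180.0):
            raise InfeasibleSpecError("closure_angle must lie in [0, 180]")

    @property
    def lobe1_ranges(self) -> list[tuple[int, int]]:
        return [(1, self.n_res_lobe1)]

    @property
    def lobe2_ranges(self) -> list[tuple[int, int]]:
        return [(self.n_res_lobe1 + 1, self.n_res_lobe1 + self.n_res_lobe2)]


@dataclass(frozen=True)
class MstSimSpec:
    """Simulated MST experiment emulating the standard protocol: a 16-step
    serial dilution measured in triplicate at 50 nM labelled protein."""

    true_Kd: float = 0.17e-6
    protein_conc: float = 50e-9
    top_conc: float = 50e-6
    n_points: int = 16
    dilution_factor: float = 2.0
    noise_sd_frac: float = 0.02
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.true_Kd, self.protein_conc, self.top_conc) <= 0:
            raise InfeasibleSpecError("concentrations must be positive")
        if self.n_points < 8:
            raise InfeasibleSpecError("need >= 8 titration points")
        if self.dilution_factor <= 1.0:
            raise InfeasibleSpecError("dilution_factor must exceed 1")


def _perp_frame(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to w and to each other."""
    a = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(a, w)) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(w, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(w, e1)
    return e1, e2


def _ring_atoms(ring_type: str) -> list[AtomRecord]:
    """Ideal regular hexagon (C-C 1.39 A) in the z=0 plane, centred at the
    origin, carrying the canonical atom names of the requested ring."""
    names = {
        "TYR6": ("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),
        "TRP6": ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"),
    }[ring_type]
    resname = "TYR" if ring_type == "TYR6" else "TRP"
    atoms = []
    for k, name in enumerate(names):
        phi = 2.0 * math.pi * k / 6.0
        atoms.append(
            AtomRecord(
                name=name,
                element="C",
                coords=np.array([RING_CC * math.cos(phi), RING_CC * math.sin(phi), 0.0]),
                residue_name=resname,
                residue_number=1,
                chain_id="A",
            )
        )
    return atoms


def _ligand_atoms_for_hydrogen(
    h: np.ndarray, p: np.ndarray, ligand: str, azimuth: float
) -> list[AtomRecord]:
    """Oxygen positions around P such that hydrogen placement puts (one of)
    the P-H hydrogens exactly at ``h``.

    Phosphite: three O at the tetrahedral angle from the P->H direction,
    spaced 120 deg in azimuth — their unit sum is exactly antiparallel to
    P->H, so the placed H lands on ``h``. Hypophosphite: complete the
    regular tetrahedron whose first two vertices are the P->H direction and
    the second-hydrogen direction; the remaining two vertices carry the O.
    """
    w = (h - p) / np.linalg.norm(h - p)
    e1, e2 = _perp_frame(w)
    atoms: list[AtomRecord] = []

    def oxygen(i: int, direction: np.ndarray) -> AtomRecord:
        return AtomRecord(
            name=f"O{i}",
            element="O",
            coords=p + P_O_BOND * direction,
            residue_name=PHOSPHITE_RESNAME if ligand == "phosphite" else HYPOPHOSPHITE_RESNAME,
            residue_number=90,
            chain_id="A",
            is_hetero=True,
        )

    if ligand == "phosphite":
        for i in range(3):
            phi = azimuth + 2.0 * math.pi * i / 3.0
            d = math.cos(_TET) * w + math.sin(_TET) * (
                math.cos(phi) * e1 + math.sin(phi) * e2
            )
            atoms.append(oxygen(i + 1, d))
    else:
        # regular tetrahedron: vertex 1 = w (the target H), 2 = second H,
        # 3 and 4 = oxygens
        verts = []
        for i in range(3):
            phi = azimuth + 2.0 * math.pi * i / 3.0
            verts.append(
                math.cos(_TET) * w
                + math.sin(_TET) * (math.cos(phi) * e1 + math.sin(phi) * e2)
            )
        atoms.append(oxygen(1, verts[1]))
        atoms.append(oxygen(2, verts[2]))
    return atoms


def make_pi_site(spec: PiSiteSpec) -> Structure:
    """Build one aromatic residue plus one P-ligand realising the spec.

    The ring lies in the z=0 plane centred at the origin; the modelled P-H
    hydrogen will land at (offset, 0, d) with the donor phosphorus placed so
    the donor-H-centroid angle equals the requested approach angle. Running
    hydrogen placement and contact detection on the result must recover
    (d, theta, offset) to numerical precision.
    """
    d = spec.plane_distance
    offset = spec.centroid_offset
    theta = math.radians(spec.approach_angle)

    h = np.array([offset, 0.0, d])
    u = -h / np.linalg.norm(h)  # H -> centroid direction
    u_perp = np.array([-u[2], 0.0, u[0]])  # in-plane-of-(h,z) perpendicular
    p_dir = math.cos(theta) * u + math.sin(theta) * u_perp
    p = h + P_H_BOND_LENGTH * p_dir
    if p[2] <= 0.2:
        raise InfeasibleSpecError(
            f"spec ({d:.2f} A, {spec.approach_angle:.0f} deg, {offset:.2f} A) "
            "places the donor phosphorus in or under the ring plane"
        )

    rng = np.random.default_rng(spec.seed)
    azimuth = float(rng.uniform(0.0, 2.0 * math.pi))
    atoms = _ring_atoms(spec.ring_type)
    resname = PHOSPHITE_RESNAME if spec.ligand == "phosphite" else HYPOPHOSPHITE_RESNAME
    atoms.append(
        AtomRecord(
            name="P",
            element="P",
            coords=p,
            residue_name=resname,
            residue_number=90,
            chain_id="A",
            is_hetero=True,
        )
    )
    atoms.extend(_ligand_atoms_for_hydrogen(h, p, spec.ligand, azimuth))
    return Structure(atoms=atoms, id=f"pi_site_{spec.ring_type}_{spec.ligand}")


def pi_site_ligand(structure: Structure) -> LigandInstance:
    """Extract the generated ligand from a pi-site fixture."""
    resname = (
        PHOSPHITE_RESNAME
        if any(a.residue_name == PHOSPHITE_RESNAME for a in structure.atoms)
        else HYPOPHOSPHITE_RESNAME
    )
    return extract_ligand(structure, resname)


def _random_walk(n: int, rng: np.random.Generator, start: np.ndarray) -> np.ndarray:
    """Self-avoiding C-alpha walk with 3.8 A steps (>= 3.0 A non-bonded)."""
    pts = [start]
    while len(pts) < n:
        for _ in range(200):
            v = rng.normal(size=3)
            v *= 3.8 / np.linalg.norm(v)
            cand = pts[-1] + v
            prev = np.array(pts[:-1]) if len(pts) > 1 else None
            if prev is None or np.min(np.linalg.norm(prev - cand, axis=1)) >= 3.0:
                pts.append(cand)
                break
        else:  # pragma: no cover - rejection failure is astronomically rare
            pts.append(pts[-1] + v)
    return np.array(pts)


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(a) * K + (1 - math.cos(a)) * (K @ K)


def make_two_lobe(spec: TwoLobeSpec) -> tuple[Structure, Structure]:
    """Open/closed pair of C-alpha traces with a known lobe-1 rotation.

    Both lobes are seeded random walks; the closed state equals the open
    state with lobe 1 rigidly rotated by ``closure_angle`` about ``axis``
    through the inter-lobe centroid. Residue numbering is contiguous:
    lobe 1 first, then lobe 2.
    """
    rng = np.random.default_rng([spec.seed, 1])
    lobe1 = _random_walk(spec.n_res_lobe1, rng, start=np.zeros(3))
    rng2 = np.random.default_rng([spec.seed, 2])
    lobe2 = _random_walk(spec.n_res_lobe2, rng2, start=np.array([28.0, 0.0, 0.0]))

    pivot = 0.5 * (lobe1.mean(axis=0) + lobe2.mean(axis=0))
    R = _rotation_about_axis(np.asarray(spec.axis, float), spec.closure_angle)
    lobe1_closed = (lobe1 - pivot) @ R.T + pivot

    def trace(l1: np.ndarray, l2: np.ndarray, sid: str) -> Structure:
        atoms = []
        for i, xyz in enumerate(np.vstack([l1, l2]), start=1):
            atoms.append(
                AtomRecord(
                    name="CA",
                    element="C",
                    coords=xyz,
                    residue_name="GLY",
                    residue_number=i,
                    chain_id="A",
                )
            )
        return Structure(atoms=atoms, id=sid)

    return (
        trace(lobe1, lobe2, "two_lobe_open"),
        trace(lobe1_closed, lobe2, "two_lobe_closed"),
    )


@dataclass
class CavityFixture:
    """A pseudo-atom shell enclosing a spherical void, with the analytic
    voxel-count reference volume for the same construction."""

    structure: Structure
    ligand: LigandInstance
    void_radius: float
    probe_radius: float

    def reference_volume(self, grid_spacing: float, padding: float = 8.0) -> float:
        """Voxel-count volume of the analytic void sphere on the same grid
        that the pocket estimator builds (ligand bounding box + padding)."""
        lig_xyz = np.array([a.coords for a in self.ligand.atoms])
        lo = lig_xyz.min(axis=0) - padding
        hi = lig_xyz.max(axis=0) + padding
        shape = tuple(int(np.ceil((hi[k] - lo[k]) / grid_spacing)) + 1 for k in range(3))
        ax = [lo[k] + grid_spacing * np.arange(shape[k]) for k in range(3)]
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        inside = X**2 + Y**2 + Z**2 <= self.void_radius**2
        return int(np.count_nonzero(inside)) * grid_spacing**3


def make_cavity(
    void_radius: float = 5.0,
    shell_thickness: float = 2.0,
    seed: int = 0,
    probe_radius: float = 1.4,
    point_spacing: float = 1.2,
) -> CavityFixture:
    """Pseudo-atom (carbon) shell enclosing a spherical void at the origin.

    Atom centres sit on concentric Fibonacci spheres starting at radius
    void_radius + r_vdW(C) + probe_radius, so that the probe-inflated
    occupied region begins exactly at ``void_radius``; layers spaced across
    ``shell_thickness`` keep the shell watertight. A small phosphite ligand
    at the centre provides the pocket seed.
    """
    from ._radii import vdw_radius

    inner = void_radius + vdw_radius("C") + probe_radius
    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = []
    serial = 0
    layer_radii = np.arange(inner, inner + shell_thickness + 1e-9, point_spacing / 2.0)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    for radius in layer_radii:
        n_pts = max(32, int(np.ceil(4.0 * math.pi * radius**2 / point_spacing**2)))
        phase = float(rng.uniform(0.0, 2.0 * math.pi))
        for k in range(n_pts):
            z = 1.0 - 2.0 * (k + 0.5) / n_pts
            r_xy = math.sqrt(max(0.0, 1.0 - z * z))
            phi = golden * k + phase
            serial += 1
            atoms.append(
                AtomRecord(
                    name="C",
                    element="C",
                    coords=radius * np.array([r_xy * math.cos(phi), r_xy * math.sin(phi), z]),
                    residue_name="SHL",
                    residue_number=serial,
                    chain_id="S",
                )
            )

    # tetrahedral phosphite seed ligand at the void centre
    p = np.zeros(3)
    w = np.array([0.0, 0.0, 1.0])
    e1, e2 = _perp_frame(w)
    lig_atoms = [
        AtomRecord(
            name="P", element="P", coords=p, residue_name=PHOSPHITE_RESNAME,
            residue_number=1, chain_id="L", is_hetero=True,
        )
    ]
    for i in range(3):
        phi = 2.0 * math.pi * i / 3.0
        d = math.cos(_TET) * w + math.sin(_TET) * (math.cos(phi) * e1 + math.sin(phi) * e2)
        lig_atoms.append(
            AtomRecord(
                name=f"O{i+1}", element="O", coords=p + P_O_BOND * d,
                residue_name=PHOSPHITE_RESNAME, residue_number=1, chain_id="L",
                is_hetero=True,
            )
        )
    structure = Structure(atoms=atoms + lig_atoms, id="synthetic_cavity")
    ligand = extract_ligand(structure, PHOSPHITE_RESNAME)
    return CavityFixture(
        structure=structure,
        ligand=ligand,
        void_radius=void_radius,
        probe_radius=probe_radius,
    )


def simulate_mst(spec: MstSimSpec) -> list[BindingCurve]:
    """Simulated replicate MST dilution series at known Kd.

    Concentrations descend as top_conc / dilution_factor^i; signals follow
    the depletion isotherm on a canonical Bound=1 / Unbound=0 scale plus
    Gaussian noise (fraction of amplitude), with an independent seeded
    substream per replicate.
    """
    conc = spec.top_conc / spec.dilution_factor ** np.arange(spec.n_points)
    params = Eq1Params(Kd=spec.true_Kd, Bound=1.0, Unbound=0.0)
    clean = eq1_model(conc, params, spec.protein_conc)
    curves = []
    for r in range(spec.n_replicates):
        rng = np.random.default_rng([spec.seed, r])
        noise = rng.normal(0.0, spec.noise_sd_frac, size=conc.size) if spec.noise_sd_frac > 0 else 0.0
        curves.append(
            BindingCurve(
                ligand_conc=conc,
                signal=clean + noise,
                replicate_id=r,
                protein_conc=spec.protein_conc,
            )
        )
    return curves


def simulate_itc(
    true_Kd: float = 289e-9,
    dH: float = -40.0,
    n_sites: float = 1.0,
    cell_protein_conc: float = 200e-6,
    syringe_ligand_conc: float = 2e-3,
    cell_volume: float = 160.0,
    n_injections: int = 32,
    injection_volume: float = 1.49,
    noise_sd_frac: float = 0.01,
    seed: int = 0,
) -> ItcTitration:
    """Simulated single-site ITC titration at known parameters.

    Defaults reproduce the standard titration geometry used throughout the
    package: 32 injections of 1.49 ul of 2 mM ligand into 160 ul of 200 uM
    protein. Heat noise is Gaussian with sd = noise_sd_frac x the largest
    absolute clean heat.
    """
    titration = ItcTitration(
        cell_protein_conc=cell_protein_conc,
        syringe_ligand_conc=syringe_ligand_conc,
        cell_volume=cell_volume,
        injection_volumes=np.full(n_injections, injection_volume),
        heats=np.zeros(n_injections),
        skip_first=True,
    )
    clean = itc_forward(true_Kd, dH, n_sites, titration)
    rng = np.random.default_rng([seed, 7])
    scale = noise_sd_frac * float(np.max(np.abs(clean)))
    noise = rng.normal(0.0, scale, size=clean.size) if scale > 0 else 0.0
    titration.heats = clean + noise
    return titration
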