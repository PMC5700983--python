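"""Buried-cavity volume on a 3-D grid with a solvent probe.

The ligand-binding pocket of a closed periplasmic binding protein is an
enclosed cavity. Its volume is estimated by voxelising a box around the
ligand, marking voxels within (vdW + probe) of any protein heavy atom as
occupied, flood-filling bulk solvent in from the box boundary, and counting
the free voxels connected to the ligand centroid that the bulk cannot
reach. Ligand atoms are excluded from the occupying set (the cavity is
measured with the ligand removed). Absolute values depend on the estimator;
comparisons between structures should use identical parameters and be read
as percent changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from ._radii import vdw_radius
from .structure_io import LigandInstance, Structure

__all__ = ["PocketParams", "PocketResult", "PocketError", "pocket_volume", "volume_change"]

_SIX_CONNECTED = ndimage.generate_binary_structure(3, 1)


class PocketError(ValueError):
    """Raised for invalid parameters or undefined volume ratios."""


@dataclass(frozen=True)
class PocketParams:
    """Grid parameters: water-sized probe (1.4 A), 0.5 A spacing, and the
    padding around the ligand bounding box defining the search region."""

    probe_radius: float = 1.4
    grid_spacing: float = 0.5
    padding: float = 8.0
    include_waters: bool = False

    def __post_init__(self) -> None:
        if min(self.probe_radius, self.grid_spacing, self.padding) <= 0:
            raise PocketError("probe_radius, grid_spacing, padding must be positive")
        if self.grid_spacing > self.probe_radius:
            raise PocketError("grid_spacing must not exceed probe_radius")


@dataclass
class PocketResult:
    """Cavity volume with the exact parameters used to compute it."""

    volume: float
    n_cavity_voxels: int
    params: PocketParams
    seed_point: np.ndarray
    flags: list[str] = field(default_factory=list)

    @property
    def open_pocket(self) -> bool:
        return "open pocket" in self.flags


def _occupancy_grid(
    atoms_xyz: np.ndarray,
    radii: np.ndarray,
    origin: np.ndarray,
    shape: tuple[int, int, int],
    spacing: float,
) -> np.ndarray:
    """Boolean grid: voxel center within radius[i] of atom i for some i."""
    nx, ny, nz = shape
    occupied = np.zeros(shape, dtype=bool)
    tree = cKDTree(atoms_xyz)
    ax = origin[0] + spacing * np.arange(nx)
    ay = origin[1] + spacing * np.arange(ny)
    az = origin[2] + spacing * np.arange(nz)
    centers = np.stack(np.meshgrid(ax, ay, az, indexing="ij"), axis=-1).reshape(-1, 3)
    rmax = float(radii.max())
    # query within the largest inflation radius, then refine per atom radius
    neighbours = tree.query_ball_point(centers, rmax, workers=-1)
    flat = occupied.reshape(-1)
    for i, idx in enumerate(neighbours):
        if not idx:
            continue
        d = np.linalg.norm(atoms_xyz[idx] - centers[i], axis=1)
        if np.any(d <= radii[idx]):
            flat[i] = True
    return occupied


def pocket_volume(
    s: Structure,
    lig: LigandInstance,
    params: PocketParams | None = None,
) -> PocketResult:
    """Volume of the enclosed cavity around (and including) the ligand site.

    Algorithm: (1) grid over the ligand bounding box plus padding;
    (2) a voxel is occupied if its center lies within (Bondi vdW radius +
    probe radius) of any protein heavy atom — ligand atoms excluded, waters
    excluded by default; (3) free voxels 6-connected to the grid boundary
    are bulk solvent; (4) the cavity is the free, non-bulk 6-connected
    component containing the ligand-centroid voxel; (5) volume =
    voxel count x spacing^3.

    If the seed voxel is occupied, the nearest free voxel within 2 A seeds
    instead and the result is flagged; if the seed component touches the
    boundary the pocket is open and volume 0 is returned with an
    "open pocket" flag.
    """
    if params is None:
        params = PocketParams()
    flags: list[str] = []
    seed_point = lig.centroid()

    protein = s.protein_heavy_atoms(include_waters=params.include_waters)
    lig_key = lig.phosphorus.residue_key()
    protein = [a for a in protein if a.residue_key() != lig_key]
    if not protein:
        raise PocketError("no protein heavy atoms to define a pocket")
    xyz = np.array([a.coords for a in protein])
    radii = np.array([vdw_radius(a.element) + params.probe_radius for a in protein])

    lig_xyz = np.array([a.coords for a in lig.atoms])
    lo = lig_xyz.min(axis=0) - params.padding
    hi = lig_xyz.max(axis=0) + params.padding
    spacing = params.grid_spacing
    shape = tuple(int(np.ceil((hi[k] - lo[k]) / spacing)) + 1 for k in range(3))

    occupied = _occupancy_grid(xyz, radii, lo, shape, spacing)
    free = ~occupied

    labels, _ = ndimage.label(free, structure=_SIX_CONNECTED)
    boundary_labels = set()
    for axis in range(3):
        for sl in (0, -1):
            face = np.take(labels, sl, axis=axis)
            boundary_labels.update(np.unique(face[face > 0]).tolist())

    seed_idx = np.round((seed_point - lo) / spacing).astype(int)
    seed_idx = np.clip(seed_idx, 0, np.array(shape) - 1)
    if occupied[tuple(seed_idx)]:
        free_idx = np.argwhere(free)
        if free_idx.size == 0:
            return PocketResult(0.0, 0, params, seed_point, ["no free voxels"])
        d = np.linalg.norm((free_idx - seed_idx) * spacing, axis=1)
        j = int(np.argmin(d))
        if d[j] > 2.0:
            return PocketResult(
                0.0, 0, params, seed_point, ["seed occupied; no free voxel within 2 A"]
            )
        seed_idx = free_idx[j]
        flags.append("seed voxel occupied; reseeded at nearest free voxel")

    seed_label = int(labels[tuple(seed_idx)])
    if seed_label in boundary_labels:
        flags.append("open pocket")
        return PocketResult(0.0, 0, params, seed_point, flags)

    n = int(np.count_nonzero(labels == seed_label))
    volume = n * spacing**3
    return PocketResult(
        volume=volume,
        n_cavity_voxels=n,
        params=params,
        seed_point=seed_point,
        flags=flags,
    )


def volume_change(a: PocketResult, b: PocketResult) -> float:
    """Signed percent change ``100 * (b - a) / a`` between two cavities.

    Both results must have been computed with identical parameters;
    comparing volumes from different grids is meaningless.
    """
    if a.params != b.params:
        raise PocketError("pocket volumes computed with different parameters")
    if a.volume == 0:
        raise PocketError("reference volume is zero; percent change undefined")
    return 100.0 * (b.volume - a.volume) / a.volume
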