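"""Rigid-body and planar geometry.

Least-squares (Kabsch) superposition, rotation angle/axis extraction, plane
fitting, and the two-state domain-motion decomposition used to quantify the
open-to-closed lobe rotation of type II periplasmic binding proteins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .structure_io import Structure, select_calpha

__all__ = [
    "Superposition",
    "PlaneFit",
    "DomainMotion",
    "GeometryError",
    "kabsch_superpose",
    "rotation_angle_axis",
    "fit_plane",
    "domain_motion",
]

DEFAULT_LOBES = {"lobe1": [[1, 84], [202, 255]], "lobe2": [[96, 196]]}


class GeometryError(ValueError):
    """Raised for degenerate or invalid geometric input."""


@dataclass
class Superposition:
    """Optimal rigid transform mapping a moving point set onto a fixed one.

    ``y ~ rotation @ x + translation`` minimises the RMSD over all proper
    rotations (reflections excluded).
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_points: int

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


@dataclass
class PlaneFit:
    """Least-squares plane: centroid, unit normal, and the RMS out-of-plane
    deviation of the fitted points."""

    centroid: np.ndarray
    normal: np.ndarray
    planarity_rms: float

    def signed_distance(self, point: np.ndarray) -> float:
        return float(np.dot(np.asarray(point, float) - self.centroid, self.normal))

    def project(self, point: np.ndarray) -> np.ndarray:
        p = np.asarray(point, float)
        return p - self.signed_distance(p) * self.normal


@dataclass
class DomainMotion:
    """Two-lobe closure decomposition.

    After aligning on the reference lobe (lobe 2), the residual rigid motion
    of lobe 1 is expressed as a screw: rotation by ``closure_angle`` about
    ``axis`` through ``axis_point`` plus a translation along the axis.
    """

    closure_angle: float
    axis: np.ndarray
    axis_point: np.ndarray
    translation_along_axis: float
    lobe1_rmsd: float
    lobe2_rmsd: float
    n_lobe1: int = 0
    n_lobe2: int = 0


def _as_points(x: Sequence, name: str) -> np.ndarray:
    pts = np.asarray(x, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise GeometryError(f"{name}: expected an (n,3) array, got {pts.shape}")
    return pts


def _is_collinear(points: np.ndarray, tol: float = 1e-10) -> bool:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return s.size < 2 or s[1] <= tol * max(s[0], 1.0)


def kabsch_superpose(moving: Sequence, fixed: Sequence) -> Superposition:
    """Least-squares rigid superposition of ``moving`` onto ``fixed``.

    Uses the SVD form of the Kabsch algorithm with the determinant
    correction that excludes reflections.
    """
    P = _as_points(moving, "moving")
    Q = _as_points(fixed, "fixed")
    if P.shape != Q.shape:
        raise GeometryError(f"length mismatch: moving {P.shape[0]} vs fixed {Q.shape[0]}")
    n = P.shape[0]
    if n < 3:
        raise GeometryError(f"need >= 3 points, got {n}")
    if _is_collinear(P) or _is_collinear(Q):
        raise GeometryError("degenerate (collinear) point set")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return Superposition(rotation=R, translation=t, rmsd=rmsd, n_points=n)


def rotation_angle_axis(rotation: np.ndarray) -> tuple[float, np.ndarray]:
    """Angle (degrees, in [0,180]) and right-handed unit axis of a rotation.

    The zero rotation returns axis (0,0,1) by convention.
    """
    R = np.asarray(rotation, dtype=float)
    if R.shape != (3, 3):
        raise GeometryError("rotation must be 3x3")
    if not np.allclose(R.T @ R, np.eye(3), atol=1e-6) or np.linalg.det(R) < 0:
        raise GeometryError("input is not a proper rotation matrix")
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    skew = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    sin_theta = np.linalg.norm(skew) / 2.0
    # atan2 form is well conditioned near 0 and pi, unlike acos alone
    angle = float(np.degrees(np.arctan2(sin_theta, cos_theta)))
    if angle < 1e-9:
        return 0.0, np.array([0.0, 0.0, 1.0])
    if angle > 180.0 - 1e-7:
        # near-pi: axis from the symmetric part, sign immaterial
        B = (R + np.eye(3)) / 2.0
        axis = np.sqrt(np.clip(np.diag(B), 0.0, None))
        k = int(np.argmax(axis))
        axis = B[:, k] / max(axis[k], 1e-300)
        axis = axis / np.linalg.norm(axis)
        return angle, axis
    axis = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    axis /= np.linalg.norm(axis)
    return angle, axis


def fit_plane(points: Sequence) -> PlaneFit:
    """Least-squares plane through >= 3 points.

    The normal is the singular vector of the centered coordinates with the
    smallest singular value, i.e. the direction minimising the sum of
    squared perpendicular distances.
    """
    pts = _as_points(points, "points")
    if pts.shape[0] < 3:
        raise GeometryError("plane fit needs >= 3 points")
    if _is_collinear(pts):
        raise GeometryError("points are collinear; plane undefined")
    centroid = pts.mean(axis=0)
    _, s, Vt = np.linalg.svd(pts - centroid)
    normal = Vt[2]
    normal = normal / np.linalg.norm(normal)
    rms = float(np.sqrt(np.mean(((pts - centroid) @ normal) ** 2)))
    return PlaneFit(centroid=centroid, normal=normal, planarity_rms=rms)


def _paired_calpha(
    a: Structure,
    b: Structure,
    chain_a: str,
    chain_b: str,
    ranges: Sequence[tuple[int, int]],
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """C-alpha pairs shared by both structures, matched on author number."""
    ca_a, num_a, _ = select_calpha(a, chain_a, ranges)
    ca_b, num_b, _ = select_calpha(b, chain_b, ranges)
    map_a = dict(zip(num_a, ca_a))
    map_b = dict(zip(num_b, ca_b))
    shared = sorted(set(map_a) & set(map_b))
    xa = np.array([map_a[n] for n in shared]) if shared else np.empty((0, 3))
    xb = np.array([map_b[n] for n in shared]) if shared else np.empty((0, 3))
    return xa, xb, shared


def domain_motion(
    open_structure: Structure,
    closed_structure: Structure,
    lobe1: Sequence[tuple[int, int]],
    lobe2: Sequence[tuple[int, int]],
    chain_open: str | None = None,
    chain_closed: str | None = None,
    min_shared: int = 10,
) -> DomainMotion:
    """Quantify domain closure between an open and a closed conformation.

    Procedure: (i) superpose the closed structure onto the open one using
    lobe-2 C-alphas (the reference lobe); (ii) on the lobe-2-aligned pair,
    superpose the lobe-1 C-alphas and report that residual rotation as the
    closure angle/axis (a simplified DynDom-style decomposition). The axis
    point is the point on the screw axis nearest the lobe-1 centroid and the
    screw translation along the axis is reported as well.

    Correspondence is by author residue number; chains default to each
    structure's first chain.
    """
    if chain_open is None:
        chain_open = open_structure.atoms[0].chain_id
    if chain_closed is None:
        chain_closed = closed_structure.atoms[0].chain_id

    l2_closed, l2_open, shared2 = _paired_calpha(
        closed_structure, open_structure, chain_closed, chain_open, lobe2
    )
    l1_closed, l1_open, shared1 = _paired_calpha(
        closed_structure, open_structure, chain_closed, chain_open, lobe1
    )
    if len(shared2) < min_shared or len(shared1) < min_shared:
        raise GeometryError(
            f"insufficient shared C-alpha pairs: lobe1 {len(shared1)}, "
            f"lobe2 {len(shared2)} (need >= {min_shared} each)"
        )

    sup2 = kabsch_superpose(l2_closed, l2_open)
    l1_closed_aligned = sup2.apply(l1_closed)

    sup1 = kabsch_superpose(l1_closed_aligned, l1_open)
    angle, axis = rotation_angle_axis(sup1.rotation)

    centroid = l1_closed_aligned.mean(axis=0)
    R, t = sup1.rotation, sup1.translation
    t_par = float(np.dot(t + (R - np.eye(3)) @ centroid, axis)) if angle > 0 else 0.0
    # point on the screw axis closest to the lobe-1 centroid:
    # solve (R - I) p = -(t - t_par * axis) in the plane perpendicular to axis
    if angle > 1e-9:
        A = R - np.eye(3)
        rhs = -(t - t_par * axis) - A @ centroid
        # least-squares in the subspace perpendicular to the axis
        p_perp, *_ = np.linalg.lstsq(A, rhs, rcond=None)
        p_perp -= np.dot(p_perp, axis) * axis
        axis_point = centroid + p_perp
    else:
        axis_point = centroid

    return DomainMotion(
        closure_angle=angle,
        axis=axis,
        axis_point=axis_point,
        translation_along_axis=t_par,
        lobe1_rmsd=sup1.rmsd,
        lobe2_rmsd=sup2.rmsd,
        n_lobe1=len(shared1),
        n_lobe2=len(shared2),
    )
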