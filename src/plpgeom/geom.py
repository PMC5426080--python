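"""Pure geometry kernel: torsions, plane fitting, rigid superposition, distances.

All angles are in degrees (crystallographic convention); radians appear only
inside the trigonometry. Coordinates are in Angstroms throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PlaneFit",
    "SuperpositionResult",
    "GeometryError",
    "torsion",
    "fit_plane",
    "kabsch_superpose",
    "distance",
    "place_atom",
]

_COLLINEAR_TOL = 1e-10


class GeometryError(ValueError):
    """Raised for degenerate geometric input (collinear points, too few atoms)."""


@dataclass(frozen=True)
class PlaneFit:
    """Total-least-squares plane through a point set.

    ``unit_normal`` has unit length; its sign is fixed toward the positive z
    axis (ties broken toward positive x, then y) so signed ring-relative
    quantities are reproducible across runs.
    """

    unit_normal: np.ndarray
    centroid: np.ndarray
    rms_out_of_plane: float


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid-body superposition of one point set onto another.

    ``rotation`` is a proper rotation (det = +1); ``rmsd`` is evaluated after
    applying ``rotation @ x + translation`` to the moving set.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int


def _as_vec(p) -> np.ndarray:
    v = np.asarray(p, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {v.shape}")
    return v


def distance(p1, p2) -> float:
    """Euclidean distance between two points, in Angstroms."""
    return float(np.linalg.norm(_as_vec(p1) - _as_vec(p2)))


def torsion(p1, p2, p3, p4) -> float:
    """Signed dihedral angle over four points, in degrees in (-180, 180].

    Uses the standard sign convention for torsion angles: looking down the
    p2->p3 axis, a positive angle is a clockwise rotation of p4 relative to
    p1. Collinear p1-p2-p3 or p2-p3-p4 leave the angle undefined and raise
    :class:`GeometryError`.
    """
    p1, p2, p3, p4 = (_as_vec(p) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if np.linalg.norm(b2) < _COLLINEAR_TOL:
        raise GeometryError("torsion undefined: central atoms coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _COLLINEAR_TOL or np.linalg.norm(n2) < _COLLINEAR_TOL:
        raise GeometryError("torsion undefined: three consecutive points are collinear")
    b2u = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2u))
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def fit_plane(points) -> PlaneFit:
    """Fit a total-least-squares plane through >= 3 points.

    The plane minimizes the sum of squared perpendicular distances (smallest
    principal direction of the centered coordinates). Collinear input has no
    unique plane and raises :class:`GeometryError`.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ValueError("fit_plane needs an (n>=3, 3) array of points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # Collinear: the two smallest singular values both vanish.
    if s[1] < _COLLINEAR_TOL * max(1.0, s[0]):
        raise GeometryError("degenerate plane: points are collinear")
    normal = vt[2]
    # Deterministic sign: toward +z, ties toward +x then +y.
    for comp in (2, 0, 1):
        if abs(normal[comp]) > 1e-12:
            if normal[comp] < 0:
                normal = -normal
            break
    normal = normal / np.linalg.norm(normal)
    rms = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return PlaneFit(unit_normal=normal, centroid=centroid, rms_out_of_plane=rms)


def kabsch_superpose(moving, fixed) -> SuperpositionResult:
    """Least-squares rigid superposition of ``moving`` onto ``fixed``.

    Returns the proper rotation (reflections corrected via the determinant
    sign of the SVD cross-covariance) and translation minimizing the RMSD,
    together with the RMSD after transformation.
    """
    mov = np.asarray(moving, dtype=float)
    fix = np.asarray(fixed, dtype=float)
    if mov.shape != fix.shape:
        raise ValueError(f"point sets differ in shape: {mov.shape} vs {fix.shape}")
    if mov.ndim != 2 or mov.shape[1] != 3 or mov.shape[0] < 3:
        raise ValueError("superposition needs at least 3 paired 3D points")
    mc = mov.mean(axis=0)
    fc = fix.mean(axis=0)
    h = (mov - mc).T @ (fix - fc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = fc - rot @ mc
    moved = mov @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - fix) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd, n_atoms=mov.shape[0])


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place a fourth atom from three reference atoms by internal coordinates.

    The new atom x sits at |x-c| = ``bond``, with bond angle b-c-x equal to
    ``angle_deg`` and torsion(a, b, c, x) equal to ``torsion_deg`` exactly
    (up to floating point). This is the standard internal-to-Cartesian
    construction used to build idealized fragments.
    """
    a, b, c = (_as_vec(p) for p in (a, b, c))
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < _COLLINEAR_TOL:
        raise GeometryError("cannot place atom: reference atoms are collinear")
    n /= nn
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n
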