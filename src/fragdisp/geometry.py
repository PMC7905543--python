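"""Core computational geometry.

Two primitives underpin the fragment displacement measure:

* the minimal-volume **oriented bounding box** (OBB) of a fragment's vertex
  set, whose center is the reproducible "fragment center", and
* **Horn's closed-form quaternion solution** of the absolute-orientation
  problem, which recovers the rigid motion between two index-corresponding
  vertex sets.

The OBB search follows the classic convex-hull strategy: every hull facet
normal is a candidate box axis (one box face flush with that facet); the
in-plane orientation is then optimized exactly by rotating calipers
(minimum-area enclosing rectangle of the projected hull).  A short
derivative-free polish over the rotation group removes the residual error
of the face-flush restriction.  The result is not guaranteed to be the
global optimum (the exact algorithm is cubic in hull size), but it is
deterministic and in practice indistinguishable from brute force — and the
only quantity consumed downstream is the box *center*, which is insensitive
to which of several near-minimal boxes is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import ConvexHull
from scipy.spatial.transform import Rotation

from .errors import (
    DegenerateGeometryError,
    RegistrationAmbiguityError,
)
from .mesh_io import RigidTransform, TriangleMesh, _canonical_quaternion

__all__ = [
    "OrientedBoundingBox",
    "RegistrationResult",
    "compute_obb",
    "obb_center",
    "horn_register",
    "rotation_angle",
]


# ---------------------------------------------------------------------------
# Oriented bounding box
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrientedBoundingBox:
    """A rectangular box at arbitrary orientation: ``center`` (mm), three
    orthonormal right-handed ``axes`` (rows), and ``half_extents`` (mm,
    sorted descending).  ``volume`` = 8 * product of half extents."""

    center: np.ndarray
    axes: np.ndarray
    half_extents: np.ndarray
    volume: float = field(init=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.center, dtype=float)
        a = np.asarray(self.axes, dtype=float)
        h = np.asarray(self.half_extents, dtype=float)
        if np.abs(a @ a.T - np.eye(3)).max() > 1e-9:
            raise DegenerateGeometryError("OBB axes are not orthonormal")
        if np.linalg.det(a) < 0:
            raise DegenerateGeometryError("OBB axes are not right-handed")
        if (h < 0).any() or (np.diff(h) > 0).any():
            raise DegenerateGeometryError(
                "OBB half-extents must be non-negative and sorted descending"
            )
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "axes", a)
        object.__setattr__(self, "half_extents", h)
        object.__setattr__(self, "volume", float(8.0 * np.prod(h)))

    def contains(self, points: np.ndarray, rtol: float = 1e-7) -> bool:
        """True if every point lies inside the box within ``rtol`` times the
        point-cloud diameter."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        local = np.abs((pts - self.center) @ self.axes.T)
        diam = float(np.linalg.norm(np.ptp(pts, axis=0))) or 1.0
        return bool((local <= self.half_extents + rtol * diam).all())


_DIM_NAMES = {0: "a single point", 1: "a line", 2: "a plane"}


def _check_rank3(points: np.ndarray) -> None:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    scale = s[0] if s[0] > 0 else 1.0
    rank = int(np.sum(s > 1e-9 * scale))
    if rank < 3:
        raise DegenerateGeometryError(
            f"point set spans only {_DIM_NAMES[rank]} (rank {rank} < 3); "
            "a 3D oriented bounding box is undefined"
        )


def _min_area_rectangle(pts2d: np.ndarray) -> tuple[float, np.ndarray]:
    """Rotating calipers: minimum-area enclosing rectangle of a planar point
    set.  Returns (area, 2x2 row matrix of rectangle axes)."""
    hull2d = ConvexHull(pts2d)
    hp = pts2d[hull2d.vertices]
    edges = np.roll(hp, -1, axis=0) - hp
    lengths = np.linalg.norm(edges, axis=1)
    dirs = edges[lengths > 0] / lengths[lengths > 0, None]
    # each hull edge direction is a candidate rectangle axis
    us = dirs
    vs = np.stack([-dirs[:, 1], dirs[:, 0]], axis=1)
    pu = hp @ us.T  # (n_hull, n_dirs)
    pv = hp @ vs.T
    areas = np.ptp(pu, axis=0) * np.ptp(pv, axis=0)
    k = int(np.argmin(areas))
    return float(areas[k]), np.stack([us[k], vs[k]])


def _box_from_rotation(points: np.ndarray, axes: np.ndarray):
    """Fit the axis extents of ``points`` along the given orthonormal row
    axes; returns (volume, center, half_extents)."""
    proj = points @ axes.T
    lo, hi = proj.min(axis=0), proj.max(axis=0)
    half = (hi - lo) / 2.0
    center = ((lo + hi) / 2.0) @ axes
    return float(8.0 * np.prod(half)), center, half


def _canonicalize(center, axes, half):
    """Sort half-extents descending, fix axis signs lexicographically, and
    rebuild the third axis by cross product so the frame is right-handed."""
    order = np.argsort(-half, kind="stable")
    half = half[order]
    axes = axes[order]
    for i in range(2):
        for comp in axes[i]:
            if comp > 0:
                break
            if comp < 0:
                axes[i] = -axes[i]
                break
    axes[2] = np.cross(axes[0], axes[1])
    return center, axes, half


def _cross_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.stack(
        [
            a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1],
            a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2],
            a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0],
        ],
        axis=1,
    )


def _rodrigues(rv: np.ndarray) -> np.ndarray:
    """Rotation matrix of a rotation vector (cheap scalar Rodrigues)."""
    angle = float(np.linalg.norm(rv))
    if angle < 1e-16:
        return np.eye(3)
    kx, ky, kz = rv / angle
    K = np.array([[0.0, -kz, ky], [kz, 0.0, -kx], [-ky, kx, 0.0]])
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def _coarse_scan(
    hull_points: np.ndarray, step_deg: float = 6.0
) -> tuple[float, np.ndarray]:
    """Vectorized scan of box orientations on a coarse grid (direction u on
    the half sphere x in-plane angle); returns (volume, axes) of the best."""
    step = np.radians(step_deg)
    thetas = np.arange(0.0, np.pi / 2 + 1e-9, step)
    phis = np.arange(0.0, 2 * np.pi, step)
    psis = np.arange(0.0, np.pi / 2, step)
    cp, sp = np.cos(phis), np.sin(phis)
    cpsi, spsi = np.cos(psis), np.sin(psis)
    best_vol = np.inf
    best_axes: np.ndarray | None = None
    for th in thetas:
        st, ct = np.sin(th), np.cos(th)
        u = np.stack([st * cp, st * sp, np.full_like(cp, ct)], axis=1)
        e1 = np.stack([-sp, cp, np.zeros_like(cp)], axis=1)
        e2 = _cross_rows(u, e1)
        wu = np.ptp(hull_points @ u.T, axis=0)
        for c_, s_ in zip(cpsi, spsi):
            v = c_ * e1 + s_ * e2
            w = _cross_rows(u, v)
            vols = (
                wu
                * np.ptp(hull_points @ v.T, axis=0)
                * np.ptp(hull_points @ w.T, axis=0)
            )
            k = int(np.argmin(vols))
            if vols[k] < best_vol:
                best_vol = float(vols[k])
                best_axes = np.stack([v[k], w[k], u[k]])
    assert best_axes is not None
    return best_vol, best_axes


def compute_obb(points: np.ndarray) -> OrientedBoundingBox:
    """Near-minimal-volume oriented bounding box of a 3D point set.

    Deterministic for fixed input.  Requires >= 4 points of full spatial
    rank; degenerate (planar/collinear) sets raise
    :class:`DegenerateGeometryError` naming the deficient dimension.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise DegenerateGeometryError(f"points must be (n, 3), got {pts.shape}")
    if len(pts) < 4:
        raise DegenerateGeometryError(f"need >= 4 points, got {len(pts)}")
    _check_rank3(pts)

    hull = ConvexHull(pts)
    hp = pts[hull.vertices]

    # candidate normals: hull facet normals, deduplicated up to sign
    normals = hull.equations[:, :3]
    normals = normals / np.linalg.norm(normals, axis=1, keepdims=True)
    signed = np.where(
        (normals[:, [0]] < 0)
        | ((normals[:, [0]] == 0) & (normals[:, [1]] < 0))
        | ((normals[:, [0]] == 0) & (normals[:, [1]] == 0) & (normals[:, [2]] < 0)),
        -normals,
        normals,
    )
    uniq = np.unique(np.round(signed, 9), axis=0)

    best: tuple[float, np.ndarray] | None = None
    for n in uniq:
        n = n / np.linalg.norm(n)
        # in-plane basis
        seed = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(n, seed)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)
        pts2d = hp @ np.stack([e1, e2]).T
        area, rect_axes = _min_area_rectangle(pts2d)
        u = rect_axes[0, 0] * e1 + rect_axes[0, 1] * e2
        v = rect_axes[1, 0] * e1 + rect_axes[1, 1] * e2
        axes = np.stack([u, v, n])
        height = float(np.ptp(hp @ n))
        vol = area * height
        if best is None or vol < best[0] - 1e-12 * best[0]:
            best = (vol, axes)

    assert best is not None

    # polish seeds: the best face-flush candidate and the best orientation
    # from a coarse global scan — the latter guards against the face-flush
    # restriction trapping the search in a non-global valley
    seeds = [best[1], _coarse_scan(hp)[1]]

    def volume_of(axes: np.ndarray) -> float:
        return float(np.prod(np.ptp(hp @ axes.T, axis=0)))

    def polish(base_axes: np.ndarray) -> tuple[float, np.ndarray]:
        def objective(rv: np.ndarray) -> float:
            return volume_of(_rodrigues(rv) @ base_axes)

        res = minimize(
            objective,
            np.zeros(3),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-13, "maxiter": 250},
        )
        if res.fun < volume_of(base_axes):
            return float(res.fun), _rodrigues(res.x) @ base_axes
        return volume_of(base_axes), base_axes

    polished = [polish(s) for s in seeds]
    axes = min(polished, key=lambda p: p[0])[1]
    # re-orthonormalize (polish keeps it orthonormal; guard roundoff)
    u_, _, vt_ = np.linalg.svd(axes)
    axes = u_ @ vt_

    _, center, half = _box_from_rotation(pts, axes)
    center, axes, half = _canonicalize(center, axes.copy(), half)
    return OrientedBoundingBox(center, axes, half)


def obb_center(mesh: TriangleMesh) -> np.ndarray:
    """The fragment center: center of the minimal-volume OBB over the mesh
    vertex set."""
    return compute_obb(mesh.vertices).center


# ---------------------------------------------------------------------------
# Horn's absolute orientation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegistrationResult:
    """The least-squares rigid motion P -> Q and its RMS residual (mm)."""

    transform: RigidTransform
    rms_residual: float


def horn_register(P: np.ndarray, Q: np.ndarray) -> RegistrationResult:
    """Closed-form least-squares rigid registration of corresponding points.

    Finds the proper rigid motion (R, t) minimizing ``sum ||R p_i + t - q_i||^2``
    via the dominant eigenvector of the 4x4 symmetric quaternion matrix built
    from the cross-covariance of the centered sets; the translation follows
    as ``t = centroid(Q) - R centroid(P)``.  Unit weights.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise RegistrationAmbiguityError(
            f"point sets must correspond index-wise: shapes {P.shape} vs {Q.shape}"
        )
    if P.ndim != 2 or P.shape[1] != 3 or len(P) < 3:
        raise RegistrationAmbiguityError(
            f"need >= 3 corresponding 3D points, got shape {P.shape}"
        )
    p_bar = P.mean(axis=0)
    q_bar = Q.mean(axis=0)
    Pc = P - p_bar
    Qc = Q - q_bar

    s = np.linalg.svd(Pc, compute_uv=False)
    scale = s[0] if s[0] > 0 else 1.0
    if np.sum(s > 1e-9 * scale) < 2:
        raise RegistrationAmbiguityError(
            "source points are collinear; the rotation about their axis is "
            "not determined"
        )

    S = Pc.T @ Qc  # cross-covariance (unnormalized)
    sxx, sxy, sxz = S[0]
    syx, syy, syz = S[1]
    szx, szy, szz = S[2]
    N = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    eigvals, eigvecs = np.linalg.eigh(N)
    q = _canonical_quaternion(eigvecs[:, -1])  # (w, x, y, z)
    transform_r = Rotation.from_quat([q[1], q[2], q[3], q[0]]).as_matrix()
    t = q_bar - transform_r @ p_bar
    residuals = P @ transform_r.T + t - Q
    rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return RegistrationResult(RigidTransform(q, t), rms)


def rotation_angle(q: np.ndarray) -> float:
    """Rotation angle of a unit quaternion, in degrees in [0, 180].

    Uses ``2 atan2(||(x, y, z)||, |w|)`` — numerically stable near 0 and
    180 degrees, and insensitive to the q vs -q sign ambiguity.
    """
    q = np.asarray(q, dtype=float)
    if q.shape != (4,):
        raise RegistrationAmbiguityError(f"quaternion must have 4 components: {q.shape}")
    norm = np.linalg.norm(q)
    if abs(norm - 1.0) > 1e-6:
        raise RegistrationAmbiguityError(f"quaternion norm {norm:.3e} is not 1")
    w = q[0]
    vec = np.linalg.norm(q[1:])
    return float(np.degrees(2.0 * np.arctan2(vec, abs(w))))
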