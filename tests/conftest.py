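"""Shared fixtures and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import ConvexHull

import fragdisp as fd


# ---------------------------------------------------------------------------
# Independent brute-force oracle: minimal AABB volume over a 2-degree
# orientation grid (direction u over the half sphere x in-plane angle).
# Upper-bounds the true minimal OBB volume; never calls package code.
# ---------------------------------------------------------------------------


def grid_min_obb_volume(points: np.ndarray, step_deg: float = 2.0) -> float:
    pts = np.asarray(points, float)
    hp = pts[ConvexHull(pts).vertices]
    step = np.radians(step_deg)
    thetas = np.arange(0.0, np.pi / 2 + 1e-9, step)
    phis = np.arange(0.0, 2 * np.pi, step)
    psis = np.arange(0.0, np.pi / 2, step)
    cp, sp = np.cos(phis), np.sin(phis)
    best = np.inf
    for th in thetas:
        st, ct = np.sin(th), np.cos(th)
        u = np.stack([st * cp, st * sp, np.full_like(cp, ct)], axis=1)
        e1 = np.stack([-sp, cp, np.zeros_like(cp)], axis=1)
        e2 = np.cross(u, e1)
        wu = np.ptp(hp @ u.T, axis=0)
        for psi in psis:
            v = np.cos(psi) * e1 + np.sin(psi) * e2
            w = np.cross(u, v)
            wv = np.ptp(hp @ v.T, axis=0)
            ww = np.ptp(hp @ w.T, axis=0)
            best = min(best, float((wu * wv * ww).min()))
    return best


# ---------------------------------------------------------------------------
# Geometry fixtures
# ---------------------------------------------------------------------------


def make_box_mesh(extents=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> fd.TriangleMesh:
    """Indexed 8-vertex / 12-face axis-aligned box mesh with one corner at
    ``origin``."""
    ex, ey, ez = extents
    ox, oy, oz = origin
    verts = np.array(
        [
            [x, y, z]
            for x in (ox, ox + ex)
            for y in (oy, oy + ey)
            for z in (oz, oz + ez)
        ]
    )
    faces = np.array(
        [
            [0, 1, 3], [0, 3, 2],  # x = ox
            [4, 6, 7], [4, 7, 5],  # x = ox+ex
            [0, 4, 5], [0, 5, 1],  # y = oy
            [2, 3, 7], [2, 7, 6],  # y = oy+ey
            [0, 2, 6], [0, 6, 4],  # z = oz
            [1, 5, 7], [1, 7, 3],  # z = oz+ez
        ]
    )
    return fd.TriangleMesh(verts, faces, name="box")


@pytest.fixture
def cube_mesh() -> fd.TriangleMesh:
    return make_box_mesh()


@pytest.fixture(scope="session")
def fixture_fragment() -> fd.TriangleMesh:
    """An irregular convex fragment (single synthetic fragment case)."""
    case = fd.generate_case(seed=11, n_fragments=2)
    return case.meshes["frag1"]


@pytest.fixture(scope="session")
def seed1_study():
    """The default simulated study at seed 1, run end to end once."""
    sim = fd.simulate_study(seed=1)
    result = fd.run_study(sim.plans, list(sim.profiles), sim.meshes, sim.poses)
    return sim, result


def random_rigid(rng: np.random.Generator) -> fd.RigidTransform:
    """Uniform random rotation (quaternion from 4D Gaussian) + Gaussian
    translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return fd.RigidTransform(q, rng.normal(scale=10.0, size=3))
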