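"""Synthetic fracture cases and experience-dependent rater plans.

The generator emulates the study material end-to-end so the whole pipeline
is exercisable without patient data:

* **Cases** are multi-fragment "metaphysis-like" solids: a 16-gon prism
  (radius 12 mm, height 24 mm — distal-radius scale) recursively cut by
  random planes into 1-6 convex polytope fragments.  Gold-standard poses
  are the assembled (identity) configuration; initial poses displace each
  fragment by a random rigid motion (translation 2-15 mm, rotation 5-45°),
  mimicking a displaced fracture awaiting reduction.
* **Rater plans** perturb the gold pose of every fragment by a translation
  of folded-normal magnitude in a uniform random direction plus a rotation
  of folded-normal angle about a uniform random axis *through the fragment
  center*, so the simulated shift (TFS) and angle (TFA) errors are
  independently controllable.  Expected error magnitudes decrease linearly
  with years of 3D-planning and clinical experience and are truncated at
  zero.
* The two printed study tables (case demographics and rater panel) ship as
  fixtures, and the default fragment-count distribution is the empirical
  distribution of included fragments per case.

Calibration
-----------
The error model is parameterized by the *univariate* improvement slopes the
study design reports (mm/year and degrees/year of planning and clinical
experience), because those are fits to one shared set of rater means, not
independent causal coefficients.  Planning and clinical years are strongly
correlated across the rater panel, so feeding the univariate slopes
directly into an additive mean structure would not reproduce them.
:meth:`RaterErrorModel.calibrated_to` therefore solves a 2x2 linear system
in the panel's design moments for the internal additive (structural)
coefficients such that noise-free univariate regressions on the panel
return exactly the configured slopes.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, HalfspaceIntersection

from .errors import FragDispError, TableValidationError
from .geometry import compute_obb
from .mesh_io import (
    PlanRow,
    PlanTable,
    RaterProfile,
    RigidTransform,
    TriangleMesh,
)

__all__ = [
    "RaterErrorModel",
    "SyntheticCase",
    "SimulatedStudy",
    "generate_case",
    "simulate_rater_plan",
    "simulate_study",
    "table1_fixture",
    "table2_fixture",
    "count_included_fragments",
    "mean_fragments",
    "default_fragment_distribution",
    "sample_fragment_counts",
    "write_study_directory",
    "read_study_directory",
]


# ---------------------------------------------------------------------------
# Packaged study tables
# ---------------------------------------------------------------------------

_TABLE1_CSV = """\
patient,age_years,sex,side,n_fragments_total,n_fragments_included,ao_classification
1,31,m,R,4,3,2R3C
2,60,m,L,4,3,2R3C
3,46,f,L,7,6,2R3C
4,53,f,L,2,2,2R3C
5,34,f,R,3,3,2R3C
6,29,f,L,1,1,2R3A
7,20,f,R,3,2,2R3C
8,15,f,R,3,2,2R3C
9,48,f,L,3,2,2R3C
10,50,f,R,2,1,2R3A
11,28,m,L,2,2,2R3B
12,67,m,R,3,2,2R3C
13,45,m,R,2,2,2R3B
14,40,m,L,2,2,2R3B
15,23,f,R,1,1,2R3B
16,23,f,L,3,2,2R3C
17,55,m,L,7,4,2R3C
18,66,m,R,3,3,2R3C
19,51,m,R,3,3,2R3C
20,51,m,L,5,5,2R3C
"""

_TABLE2_ROWS = [
    ("1", "SS", 24.0, 10.0),
    ("2", "BE", None, 2.0),
    ("3", "BE", None, 3.0),
    ("4", "SOR", 6.0, 1.5),
    ("5", "SOR", 6.0, 1.0),
    ("6", "SOR", 7.0, 0.0),
    ("7", "JOR", 1.5, 0.0),
    ("8", "JOR", 3.0, 0.0),
    ("9", "JOR", 1.5, 0.0),
]


def table1_fixture() -> pd.DataFrame:
    """Case demographics of the 20 study fractures (age, sex, side, total and
    statistically included fragment counts, AO/OTA class)."""
    return pd.read_csv(io.StringIO(_TABLE1_CSV))


def table2_fixture() -> list[RaterProfile]:
    """The nine-rater panel: 1 senior surgeon (gold standard), 2 biomedical
    engineers, 3 senior and 3 junior orthopedic residents."""
    return [RaterProfile(*row) for row in _TABLE2_ROWS]


_FRAGMENT_COLUMNS = {
    "total": "n_fragments_total",
    "included": "n_fragments_included",
}


def count_included_fragments(table1: pd.DataFrame) -> int:
    """Total number of fragments entering the statistics."""
    col = _FRAGMENT_COLUMNS["included"]
    if col not in table1.columns:
        raise TableValidationError(f"table lacks the {col!r} column")
    return int(table1[col].sum())


def mean_fragments(table1: pd.DataFrame, which: str = "total") -> float:
    """Mean fragments per case, of the ``"total"`` or ``"included"`` count."""
    if which not in _FRAGMENT_COLUMNS:
        raise TableValidationError(f"which must be 'total' or 'included', got {which!r}")
    col = _FRAGMENT_COLUMNS[which]
    if col not in table1.columns:
        raise TableValidationError(f"table lacks the {col!r} column")
    return float(table1[col].mean())


# ---------------------------------------------------------------------------
# Rater error model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RaterErrorModel:
    """Linear experience-dependent reduction-error model.

    Slopes are expressed as the expected *univariate* improvement per year
    (mm/year for TFS, degrees/year for TFA) as recovered by regressing rater
    means on one experience variable at a time; ``calibrated_to`` converts
    them to the internal additive coefficients for a concrete rater panel.
    Error magnitudes are folded normal, hence never negative.
    """

    tfs_baseline: float = 5.0  # mm, expected shift error at zero experience
    tfs_slope_planning: float = 0.943  # mm per year of 3D-planning experience
    tfs_slope_clinical: float = 0.560  # mm per year of clinical experience
    tfa_baseline: float = 12.0  # degrees at zero experience
    tfa_slope_planning: float = 2.472  # degrees per planning year
    tfa_slope_clinical: float = 1.394  # degrees per clinical year
    noise_sd_tfs: float = 0.6  # mm, per-fragment spread
    noise_sd_tfa: float = 1.5  # degrees, per-fragment spread
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("tfs_baseline", "tfa_baseline", "noise_sd_tfs", "noise_sd_tfa"):
            if getattr(self, name) < 0:
                raise FragDispError(f"{name} must be >= 0")

    def expected_errors(self, profile: RaterProfile) -> tuple[float, float]:
        """Expected (TFS mm, TFA degrees) error magnitudes for one rater,
        truncated at zero."""
        p = profile.planning_years
        c = profile.clinical_years if profile.clinical_years is not None else 0.0
        mu_tfs = max(0.0, self.tfs_baseline - self.tfs_slope_planning * p
                     - self.tfs_slope_clinical * c)
        mu_tfa = max(0.0, self.tfa_baseline - self.tfa_slope_planning * p
                     - self.tfa_slope_clinical * c)
        return mu_tfs, mu_tfa

    def calibrated_to(self, profiles: list[RaterProfile]) -> "RaterErrorModel":
        """Return a copy whose slope fields hold the additive structural
        coefficients for this panel, chosen so that noise-free univariate
        fits on the panel recover the configured slopes exactly.

        The gold-standard rater (SS) is excluded, as it is from the study
        regressions.  Raters without clinical years contribute zero clinical
        effect to the planning fit and are dropped from the clinical fit.
        """
        panel = [p for p in profiles if p.profession != "SS"]
        p_all = np.array([r.planning_years for r in panel], dtype=float)
        c_all = np.array(
            [r.clinical_years if r.clinical_years is not None else 0.0 for r in panel]
        )
        clin = [r for r in panel if r.clinical_years is not None]
        p_cl = np.array([r.planning_years for r in clin], dtype=float)
        c_cl = np.array([r.clinical_years for r in clin], dtype=float)

        var_p = float(np.var(p_all))
        if var_p == 0 or len(clin) < 2 or float(np.var(c_cl)) == 0:
            return self  # panel cannot identify both effects; keep slopes as-is
        cov_cp = float(np.mean((p_all - p_all.mean()) * (c_all - c_all.mean())))
        cov_pc = float(np.mean((p_cl - p_cl.mean()) * (c_cl - c_cl.mean())))
        var_c = float(np.var(c_cl))
        # [s_p + s_c cov_cp/var_p = S_p] and [s_c + s_p cov_pc/var_c = S_c]
        design = np.array([[1.0, cov_cp / var_p], [cov_pc / var_c, 1.0]])
        s_tfs = np.linalg.solve(
            design, [self.tfs_slope_planning, self.tfs_slope_clinical]
        )
        s_tfa = np.linalg.solve(
            design, [self.tfa_slope_planning, self.tfa_slope_clinical]
        )
        return dataclasses.replace(
            self,
            tfs_slope_planning=float(s_tfs[0]),
            tfs_slope_clinical=float(s_tfs[1]),
            tfa_slope_planning=float(s_tfa[0]),
            tfa_slope_clinical=float(s_tfa[1]),
        )


# ---------------------------------------------------------------------------
# Case geometry: recursive plane cuts of a convex "metaphysis" solid
# ---------------------------------------------------------------------------

_PRISM_RADIUS = 12.0  # mm
_PRISM_HALF_HEIGHT = 12.0  # mm
_PRISM_SIDES = 16
_MIN_FRAGMENT_VOLUME = 150.0  # mm^3, rejects sliver cuts
_MAX_CUT_RETRIES = 100


def _base_solid() -> tuple[np.ndarray, np.ndarray]:
    """The uncut solid as halfspaces A x <= b: a regular 16-gon prism."""
    angles = 2.0 * np.pi * np.arange(_PRISM_SIDES) / _PRISM_SIDES
    side_normals = np.stack(
        [np.cos(angles), np.sin(angles), np.zeros_like(angles)], axis=1
    )
    A = np.vstack([side_normals, [[0.0, 0.0, 1.0]], [[0.0, 0.0, -1.0]]])
    b = np.concatenate(
        [np.full(_PRISM_SIDES, _PRISM_RADIUS), [_PRISM_HALF_HEIGHT] * 2]
    )
    return A, b


def _chebyshev_center(A: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    """Deepest interior point of the polytope {A x <= b} and its radius."""
    norms = np.linalg.norm(A, axis=1)
    res = linprog(
        c=[0.0, 0.0, 0.0, -1.0],
        A_ub=np.hstack([A, norms[:, None]]),
        b_ub=b,
        bounds=[(None, None)] * 3 + [(0, None)],
        method="highs",
    )
    if not res.success:
        return np.zeros(3), -1.0
    return res.x[:3], float(res.x[3])


def _polytope_vertices(A: np.ndarray, b: np.ndarray) -> np.ndarray | None:
    center, radius = _chebyshev_center(A, b)
    if radius <= 1e-6:
        return None
    hs = HalfspaceIntersection(np.hstack([A, -b[:, None]]), center)
    verts = np.unique(np.round(hs.intersections, 9), axis=0)
    if len(verts) < 4:
        return None
    return verts


def _polytope_mesh(verts: np.ndarray, name: str) -> TriangleMesh:
    """Triangulated outward-oriented surface of a convex vertex set."""
    hull = ConvexHull(verts)
    centroid = verts[hull.vertices].mean(axis=0)
    faces = []
    for simplex in hull.simplices:
        a, bb, c = verts[simplex]
        normal = np.cross(bb - a, c - a)
        if normal @ ((a + bb + c) / 3.0 - centroid) < 0:
            simplex = simplex[::-1]
        faces.append(simplex)
    return TriangleMesh(verts, np.array(faces, dtype=np.int64), name=name)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
        if n > 1e-12:
            return v / n


@dataclass(frozen=True)
class SyntheticCase:
    """One simulated fracture: fragment meshes, the gold (reduced) poses and
    the initial (displaced) poses, keyed by fragment id."""

    case_id: str
    meshes: dict[str, TriangleMesh]
    gold_poses: dict[str, RigidTransform]
    initial_poses: dict[str, RigidTransform]

    @property
    def fragment_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.meshes))


def generate_case(
    seed: int, n_fragments: int, case_id: str | None = None
) -> SyntheticCase:
    """Generate one multi-fragment case, deterministically for a fixed seed.

    The solid is cut ``n_fragments - 1`` times; each cut splits the
    currently largest piece by a random plane through a random interior
    point, rejecting cuts that leave a sliver.
    """
    if not 1 <= n_fragments <= 6:
        raise FragDispError(
            f"n_fragments must be in 1..6 (study range), got {n_fragments}"
        )
    rng = np.random.default_rng(seed)
    case_id = case_id if case_id is not None else f"case{seed}"

    A0, b0 = _base_solid()
    pieces: list[tuple[np.ndarray, np.ndarray, np.ndarray, float]] = []
    v0 = _polytope_vertices(A0, b0)
    assert v0 is not None
    pieces.append((A0, b0, v0, float(ConvexHull(v0).volume)))

    while len(pieces) < n_fragments:
        pieces.sort(key=lambda p: -p[3])
        A, b, verts, _ = pieces[0]
        for _attempt in range(_MAX_CUT_RETRIES):
            normal = _random_unit(rng)
            weights = rng.dirichlet(np.ones(len(verts)))
            point = weights @ verts
            offset = float(normal @ point)
            lo = (np.vstack([A, normal]), np.append(b, offset))
            hi = (np.vstack([A, -normal]), np.append(b, -offset))
            v_lo = _polytope_vertices(*lo)
            v_hi = _polytope_vertices(*hi)
            if v_lo is None or v_hi is None:
                continue
            vol_lo = float(ConvexHull(v_lo).volume)
            vol_hi = float(ConvexHull(v_hi).volume)
            if min(vol_lo, vol_hi) < _MIN_FRAGMENT_VOLUME:
                continue
            pieces[0] = (lo[0], lo[1], v_lo, vol_lo)
            pieces.append((hi[0], hi[1], v_hi, vol_hi))
            break
        else:  # pragma: no cover - prism volume >> threshold
            raise FragDispError("could not find a non-sliver cut")

    meshes: dict[str, TriangleMesh] = {}
    gold: dict[str, RigidTransform] = {}
    initial: dict[str, RigidTransform] = {}
    for i, (_, _, verts, _) in enumerate(pieces, start=1):
        frag_id = f"frag{i}"
        mesh = _polytope_mesh(verts, name=f"{case_id}_{frag_id}")
        meshes[frag_id] = mesh
        gold[frag_id] = RigidTransform.identity()
        # displaced pre-reduction pose: rotation 5-45 deg about an axis
        # through the fragment centroid, then a 2-15 mm translation
        angle = np.radians(rng.uniform(5.0, 45.0))
        axis = _random_unit(rng)
        shift = rng.uniform(2.0, 15.0) * _random_unit(rng)
        centroid = mesh.vertices.mean(axis=0)
        rot = _axis_angle_matrix(axis, angle)
        initial[frag_id] = RigidTransform.from_rotation_translation(
            rot, centroid - rot @ centroid + shift
        )
    return SyntheticCase(case_id, meshes, gold, initial)


def _axis_angle_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(angle_rad * np.asarray(axis)).as_matrix()


# ---------------------------------------------------------------------------
# Rater plan simulation
# ---------------------------------------------------------------------------


def simulate_rater_plan(
    case: SyntheticCase,
    profile: RaterProfile,
    model: RaterErrorModel,
    rng: np.random.Generator | None = None,
    centers: dict[str, np.ndarray] | None = None,
) -> dict[str, RigidTransform]:
    """Simulate one rater's reduction plan for one case.

    Each fragment's gold pose is perturbed by a translation of magnitude
    ``|N(mu_tfs, noise_sd_tfs)|`` in a uniform random direction and a
    rotation of angle ``|N(mu_tfa, noise_sd_tfa)|`` about a uniform random
    axis through the fragment center, so the measured deviation from gold
    is exactly the drawn (shift, angle) pair.

    ``model`` is used as-is: pass a panel-calibrated model (see
    :meth:`RaterErrorModel.calibrated_to`) to target the univariate slopes.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    mu_tfs, mu_tfa = model.expected_errors(profile)
    poses: dict[str, RigidTransform] = {}
    for frag_id in case.fragment_ids:
        gold = case.gold_poses[frag_id]
        if centers is not None and frag_id in centers:
            center = centers[frag_id]
        else:
            center = compute_obb(gold.apply(case.meshes[frag_id].vertices)).center
        mag = abs(rng.normal(mu_tfs, model.noise_sd_tfs)) if model.noise_sd_tfs > 0 else mu_tfs
        direction = _random_unit(rng)
        ang = abs(rng.normal(mu_tfa, model.noise_sd_tfa)) if model.noise_sd_tfa > 0 else mu_tfa
        axis = _random_unit(rng)
        rot = _axis_angle_matrix(axis, np.radians(ang))
        # rotation about the fragment center, then the shift
        t = center - rot @ center + mag * direction
        deviation = RigidTransform.from_rotation_translation(rot, t)
        poses[frag_id] = deviation.compose(gold)
    return poses


# ---------------------------------------------------------------------------
# Whole-study simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulatedStudy:
    """A self-contained in-memory study, consumable by
    :func:`fragdisp.study_analysis.run_study`."""

    cases: tuple[SyntheticCase, ...]
    profiles: tuple[RaterProfile, ...]
    plans: PlanTable
    poses: dict[str, RigidTransform]
    meshes: dict[tuple[str, str], TriangleMesh]
    model: RaterErrorModel  # the structural (panel-calibrated) model used


def default_fragment_distribution() -> tuple[np.ndarray, np.ndarray]:
    """Empirical distribution of included fragments per case from the study
    demographics table: (counts 1..6, probabilities)."""
    included = table1_fixture()["n_fragments_included"].to_numpy()
    values, freq = np.unique(included, return_counts=True)
    return values, freq / freq.sum()


def sample_fragment_counts(rng: np.random.Generator, n_cases: int) -> np.ndarray:
    """Draw per-case fragment counts from the configured distribution."""
    values, probs = default_fragment_distribution()
    return rng.choice(values, size=n_cases, p=probs)


def simulate_study(
    seed: int,
    profiles: list[RaterProfile] | None = None,
    n_cases: int = 20,
    model: RaterErrorModel | None = None,
    calibrate: bool = True,
) -> SimulatedStudy:
    """Simulate the full study: ``n_cases`` fracture cases and one reduction
    plan per rater and case.

    The gold-standard rater (SS) is assigned the gold poses verbatim; every
    other rater's plan is drawn from the error model (panel-calibrated by
    default).  Fragment counts per case are sampled from the demographics
    table's included-fragment distribution.
    """
    profiles = list(profiles) if profiles is not None else table2_fixture()
    gold_raters = [p for p in profiles if p.profession == "SS"]
    if len(gold_raters) != 1:
        raise TableValidationError(
            f"exactly one SS (gold standard) required, got {len(gold_raters)}"
        )
    gold_id = gold_raters[0].rater_id
    base_model = model if model is not None else RaterErrorModel()
    struct_model = base_model.calibrated_to(profiles) if calibrate else base_model

    rng = np.random.default_rng(seed)
    counts = sample_fragment_counts(rng, n_cases)

    cases: list[SyntheticCase] = []
    centers_by_case: dict[str, dict[str, np.ndarray]] = {}
    for i, k in enumerate(counts, start=1):
        case_seed = int(rng.integers(0, 2**31 - 1))
        case = generate_case(case_seed, int(k), case_id=f"case{i:02d}")
        cases.append(case)
        centers_by_case[case.case_id] = {
            fid: compute_obb(
                case.gold_poses[fid].apply(case.meshes[fid].vertices)
            ).center
            for fid in case.fragment_ids
        }

    rows: list[PlanRow] = []
    poses: dict[str, RigidTransform] = {}
    meshes: dict[tuple[str, str], TriangleMesh] = {}
    for case in cases:
        for fid in case.fragment_ids:
            meshes[(case.case_id, fid)] = case.meshes[fid]
            ref = f"{gold_id}:{case.case_id}:{fid}"
            poses[ref] = case.gold_poses[fid]
            rows.append(PlanRow(gold_id, case.case_id, fid, ref))
    for profile in profiles:
        if profile.rater_id == gold_id:
            continue
        rater_rng = np.random.default_rng(int(rng.integers(0, 2**31 - 1)))
        for case in cases:
            plan = simulate_rater_plan(
                case,
                profile,
                struct_model,
                rng=rater_rng,
                centers=centers_by_case[case.case_id],
            )
            for fid, pose in plan.items():
                ref = f"{profile.rater_id}:{case.case_id}:{fid}"
                poses[ref] = pose
                rows.append(PlanRow(profile.rater_id, case.case_id, fid, ref))

    return SimulatedStudy(
        cases=tuple(cases),
        profiles=tuple(profiles),
        plans=PlanTable(tuple(rows), gold_id),
        poses=poses,
        meshes=meshes,
        model=struct_model,
    )


# ---------------------------------------------------------------------------
# Study directory round-trip (CLI surface)
# ---------------------------------------------------------------------------


def write_study_directory(sim: SimulatedStudy, out_dir) -> None:
    """Write a simulated study as files: ``meshes/*.stl``, ``poses/*.json``,
    ``plans.csv`` (pose_path column pointing at the pose files) and
    ``raters.csv``."""
    from pathlib import Path

    from . import mesh_io

    out = Path(out_dir)
    (out / "meshes").mkdir(parents=True, exist_ok=True)
    (out / "poses").mkdir(exist_ok=True)
    for (case_id, fid), mesh in sim.meshes.items():
        mesh_io.write_mesh(mesh, out / "meshes" / f"{case_id}_{fid}.stl")
    rows = []
    for row in sim.plans.rows:
        rel = f"poses/{row.rater_id}_{row.case_id}_{row.fragment_id}.json"
        mesh_io.write_pose(sim.poses[row.pose_ref], out / rel)
        rows.append(PlanRow(row.rater_id, row.case_id, row.fragment_id, rel))
    mesh_io.write_plan_table(
        PlanTable(tuple(rows), sim.plans.gold_rater_id), out / "plans.csv"
    )
    mesh_io.write_rater_table(sim.profiles, out / "raters.csv")


def read_study_directory(study_dir, gold_rater_id: str):
    """Load a study directory written by :func:`write_study_directory`.

    Returns ``(plans, profiles, meshes, poses)`` ready for ``run_study``.
    """
    from pathlib import Path

    from . import mesh_io

    root = Path(study_dir)
    plans = mesh_io.read_plan_table(root / "plans.csv", gold_rater_id)
    profiles = mesh_io.read_rater_table(root / "raters.csv")
    poses = {
        row.pose_ref: mesh_io.read_pose(root / row.pose_ref) for row in plans.rows
    }
    meshes = {}
    for row in plans.rows:
        key = (row.case_id, row.fragment_id)
        if key not in meshes:
            meshes[key] = mesh_io.read_mesh(
                root / "meshes" / f"{row.case_id}_{row.fragment_id}.stl"
            )
    return plans, profiles, meshes, poses
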