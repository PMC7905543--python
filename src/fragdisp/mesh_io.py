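"""On-disk artifacts: fragment meshes, rigid poses, plan and rater tables, results.

Conventions
-----------
* Meshes are triangulated surfaces in millimetres, read from STL (ASCII or
  binary) or PLY (ASCII).  Vertices are **never** merged or reordered on
  input: the vertex order is the identity correspondence between two poses
  of the same fragment, which downstream registration relies on.
* Poses are proper rigid motions stored as JSON
  ``{"matrix": [[...4x4...]], "units": "mm"}`` with the action
  ``v' = R v + t`` in right-handed axes.  Reflections are rejected, not
  repaired: a reduction plan cannot mirror a bone fragment.
* Tables are comma-separated UTF-8 with a header row.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import trimesh
from scipy.spatial.transform import Rotation

from .errors import (
    EmptyMeshError,
    InvalidPoseError,
    MeshFormatError,
    TableValidationError,
)

logger = logging.getLogger("fragdisp")

PROFESSIONS = ("SS", "BE", "SOR", "JOR")
_MESH_EXTENSIONS = (".stl", ".ply")

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TriangleMesh:
    """A triangulated fragment surface in mm.

    ``vertices`` keep their file order; two poses of the same fragment are
    matched index-wise, so duplicate vertices (as produced by STL) are kept.
    """

    vertices: np.ndarray  # (n, 3) float64, mm
    faces: np.ndarray  # (m, 3) int
    name: str = ""

    def __post_init__(self) -> None:
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=float))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise MeshFormatError(f"vertices must be (n, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise MeshFormatError(f"faces must be (m, 3), got {f.shape}")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise MeshFormatError(
                f"face index out of range (mesh has {len(v)} vertices)"
            )
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def diameter(self) -> float:
        """Axis-aligned bounding-box diagonal — the length scale used for
        relative tolerances (cheap, within a factor sqrt(3) of the true
        point-set diameter)."""
        if not len(self.vertices):
            return 0.0
        return float(np.linalg.norm(np.ptp(self.vertices, axis=0)))

    def transformed(self, pose: "RigidTransform") -> "TriangleMesh":
        return TriangleMesh(pose.apply(self.vertices), self.faces, self.name)


def _canonical_quaternion(q: np.ndarray) -> np.ndarray:
    """Normalize and fix the sign ambiguity (q and -q are the same rotation)
    by requiring w >= 0; for w == 0 the first non-zero component is positive."""
    q = np.asarray(q, dtype=float)
    q = q / np.linalg.norm(q)
    for comp in q:
        if comp > 0:
            return q
        if comp < 0:
            return -q
    return q


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``v' = R v + t`` (rotation as unit quaternion
    ``(w, x, y, z)`` with w >= 0; translation in mm)."""

    quaternion: np.ndarray  # (4,) scalar-first, unit norm, w >= 0
    translation: np.ndarray  # (3,) mm

    def __post_init__(self) -> None:
        q = np.asarray(self.quaternion, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if q.shape != (4,):
            raise InvalidPoseError(f"quaternion must have 4 components, got {q.shape}")
        if t.shape != (3,):
            raise InvalidPoseError(f"translation must have 3 components, got {t.shape}")
        norm = np.linalg.norm(q)
        if abs(norm - 1.0) > 1e-6:
            raise InvalidPoseError(f"quaternion norm {norm:.3e} is not 1")
        object.__setattr__(self, "quaternion", _canonical_quaternion(q))
        object.__setattr__(self, "translation", t.copy())

    # -- constructors -------------------------------------------------------

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.array([1.0, 0.0, 0.0, 0.0]), np.zeros(3))

    @classmethod
    def from_rotation_translation(
        cls, rotation: np.ndarray, translation: Sequence[float]
    ) -> "RigidTransform":
        """Build from a 3x3 rotation matrix and a translation vector.

        The rotation block must be orthonormal with determinant +1 within
        1e-6; it is then re-orthonormalized (nearest rotation in the
        Frobenius sense, via SVD) so the stored quaternion is unit to 1e-12.
        """
        rot = np.asarray(rotation, dtype=float)
        if rot.shape != (3, 3):
            raise InvalidPoseError(f"rotation must be 3x3, got {rot.shape}")
        if np.linalg.det(rot) <= 0:
            raise InvalidPoseError(
                "rotation block has non-positive determinant (reflection); "
                "a reduction plan cannot mirror a fragment"
            )
        defect = np.abs(rot.T @ rot - np.eye(3)).max()
        if defect > 1e-6:
            raise InvalidPoseError(
                f"rotation block is not orthonormal (defect {defect:.3e} > 1e-6)"
            )
        u, _, vt = np.linalg.svd(rot)
        nearest = u @ vt
        if np.linalg.det(nearest) < 0:  # pragma: no cover - blocked by det check
            raise InvalidPoseError("projection produced a reflection")
        q_xyzw = Rotation.from_matrix(nearest).as_quat()
        q = np.array([q_xyzw[3], q_xyzw[0], q_xyzw[1], q_xyzw[2]])
        return cls(q, np.asarray(translation, dtype=float))

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        """Build from a 4x4 homogeneous matrix (row-major, v' = R v + t)."""
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise InvalidPoseError(f"matrix must be 4x4, got {m.shape}")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=1e-9):
            raise InvalidPoseError(f"bottom row must be [0, 0, 0, 1], got {m[3]}")
        return cls.from_rotation_translation(m[:3, :3], m[:3, 3])

    # -- conversions --------------------------------------------------------

    @property
    def rotation_matrix(self) -> np.ndarray:
        w, x, y, z = self.quaternion
        return Rotation.from_quat([x, y, z, w]).as_matrix()

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation_matrix
        m[:3, 3] = self.translation
        return m

    # -- group operations ---------------------------------------------------

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map one point (3,) or a stack (n, 3) through the motion."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation_matrix.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self ∘ other``: apply ``other`` first, then ``self``."""
        r = self.rotation_matrix @ other.rotation_matrix
        t = self.rotation_matrix @ other.translation + self.translation
        return RigidTransform.from_rotation_translation(r, t)

    def inverse(self) -> "RigidTransform":
        r = self.rotation_matrix.T
        return RigidTransform.from_rotation_translation(r, -r @ self.translation)


@dataclass(frozen=True)
class RaterProfile:
    """One study rater: profession group and the two experience variables.

    ``clinical_years`` is ``None`` for biomedical engineers, who have no
    clinical experience by definition.
    """

    rater_id: str
    profession: str
    clinical_years: float | None
    planning_years: float

    def __post_init__(self) -> None:
        if self.profession not in PROFESSIONS:
            raise TableValidationError(
                f"rater {self.rater_id!r}: unknown profession code "
                f"{self.profession!r} (expected one of {PROFESSIONS})"
            )
        for label, value in (
            ("clinical_years", self.clinical_years),
            ("planning_years", self.planning_years),
        ):
            if value is None:
                continue
            if not math.isfinite(value) or value < 0:
                raise TableValidationError(
                    f"rater {self.rater_id!r}: {label} must be finite and "
                    f">= 0, got {value!r}"
                )


@dataclass(frozen=True)
class PlanRow:
    rater_id: str
    case_id: str
    fragment_id: str
    pose_ref: str


@dataclass(frozen=True)
class PlanTable:
    """All (rater, case, fragment) -> pose assignments of one study, with a
    designated gold-standard rater whose plan every fragment must carry."""

    rows: tuple[PlanRow, ...]
    gold_rater_id: str

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str, str], int] = {}
        for i, row in enumerate(self.rows):
            key = (row.rater_id, row.case_id, row.fragment_id)
            if key in seen:
                raise TableValidationError(
                    f"row {i + 1}: duplicate (rater, case, fragment) key {key}; "
                    f"first seen at row {seen[key] + 1}"
                )
            seen[key] = i
        gold_pairs = {
            (r.case_id, r.fragment_id)
            for r in self.rows
            if r.rater_id == self.gold_rater_id
        }
        for i, row in enumerate(self.rows):
            if row.rater_id == self.gold_rater_id:
                continue
            if (row.case_id, row.fragment_id) not in gold_pairs:
                raise TableValidationError(
                    f"row {i + 1}: fragment ({row.case_id}, {row.fragment_id}) "
                    f"planned by rater {row.rater_id!r} has no gold-standard "
                    f"plan from rater {self.gold_rater_id!r}"
                )

    @property
    def rater_ids(self) -> tuple[str, ...]:
        out: list[str] = []
        for row in self.rows:
            if row.rater_id not in out:
                out.append(row.rater_id)
        return tuple(out)

    def rows_for(self, rater_id: str) -> tuple[PlanRow, ...]:
        return tuple(r for r in self.rows if r.rater_id == rater_id)


# ---------------------------------------------------------------------------
# Mesh I/O
# ---------------------------------------------------------------------------


def read_mesh(path: str | Path, name: str | None = None) -> TriangleMesh:
    """Read an STL (ASCII/binary) or PLY (ASCII) fragment surface.

    Duplicate vertices are NOT merged: STL yields 3 vertices per facet, PLY
    its indexed vertex list, exactly as stored.
    """
    path = Path(path)
    if path.suffix.lower() not in _MESH_EXTENSIONS:
        raise MeshFormatError(
            f"{path}: unsupported extension {path.suffix!r} (expected .stl or .ply)"
        )
    if not path.exists():
        raise MeshFormatError(f"{path}: file not found")
    try:
        loaded = trimesh.load(
            str(path), process=False, maintain_order=True, force="mesh"
        )
    except Exception as exc:
        raise MeshFormatError(f"{path}: could not parse mesh ({exc})") from exc
    faces = np.asarray(getattr(loaded, "faces", np.zeros((0, 3), dtype=int)))
    if faces.size == 0:
        raise EmptyMeshError(f"{path}: mesh has no faces")
    return TriangleMesh(
        np.asarray(loaded.vertices, dtype=float),
        faces.astype(np.int64),
        name=name if name is not None else path.stem,
    )


def write_mesh(mesh: TriangleMesh, path: str | Path) -> None:
    """Write a mesh as ASCII STL or ASCII PLY, by extension."""
    path = Path(path)
    if path.suffix.lower() not in _MESH_EXTENSIONS:
        raise MeshFormatError(f"{path}: unsupported extension {path.suffix!r}")
    tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    if path.suffix.lower() == ".ply":
        path.write_bytes(tm.export(file_type="ply", encoding="ascii"))
    else:
        path.write_text(trimesh.exchange.stl.export_stl_ascii(tm))


# ---------------------------------------------------------------------------
# Pose I/O
# ---------------------------------------------------------------------------


def read_pose(path: str | Path) -> RigidTransform:
    """Read a rigid pose from JSON ``{"matrix": [[...4x4...]], "units": "mm"}``."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise InvalidPoseError(f"{path}: could not read pose JSON ({exc})") from exc
    if not isinstance(payload, dict) or "matrix" not in payload:
        raise InvalidPoseError(f"{path}: pose JSON must contain a 'matrix' key")
    units = payload.get("units", "mm")
    if units != "mm":
        raise InvalidPoseError(f"{path}: unsupported units {units!r} (expected 'mm')")
    try:
        return RigidTransform.from_matrix(np.asarray(payload["matrix"], dtype=float))
    except InvalidPoseError as exc:
        raise InvalidPoseError(f"{path}: {exc}") from exc


def write_pose(pose: RigidTransform, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({"matrix": pose.as_matrix().tolist(), "units": "mm"}, indent=1)
    )


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

_PLAN_COLUMNS = ["rater_id", "case_id", "fragment_id", "pose_path"]
_RATER_COLUMNS = ["rater_id", "profession", "clinical_years", "planning_years"]


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:
        raise TableValidationError(f"{path}: could not read CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableValidationError(f"{path}: missing column(s) {missing}")
    return df


def read_plan_table(path: str | Path, gold_rater_id: str) -> PlanTable:
    """Read ``rater_id,case_id,fragment_id,pose_path`` rows and validate that
    the designated gold rater covers every planned fragment."""
    df = _read_csv(path, _PLAN_COLUMNS)
    rows = tuple(
        PlanRow(r.rater_id, r.case_id, r.fragment_id, r.pose_path)
        for r in df.itertuples(index=False)
    )
    return PlanTable(rows, gold_rater_id)


def read_rater_table(path: str | Path) -> list[RaterProfile]:
    """Read ``rater_id,profession,clinical_years,planning_years`` rows.

    An empty ``clinical_years`` cell means the rater has none (BE).  At most
    one senior surgeon (SS) is permitted — the study has one gold standard.
    """
    df = _read_csv(path, _RATER_COLUMNS)
    profiles: list[RaterProfile] = []
    for i, r in enumerate(df.itertuples(index=False)):
        try:
            clinical = float(r.clinical_years) if r.clinical_years.strip() else None
            planning = float(r.planning_years) if r.planning_years.strip() else 0.0
        except ValueError as exc:
            raise TableValidationError(f"row {i + 1}: non-numeric years ({exc})") from exc
        try:
            profiles.append(
                RaterProfile(r.rater_id, r.profession.strip(), clinical, planning)
            )
        except TableValidationError as exc:
            raise TableValidationError(f"row {i + 1}: {exc}") from exc
    seen_ids = [p.rater_id for p in profiles]
    if len(set(seen_ids)) != len(seen_ids):
        dupes = sorted({x for x in seen_ids if seen_ids.count(x) > 1})
        raise TableValidationError(f"duplicate rater_id(s): {dupes}")
    n_ss = sum(p.profession == "SS" for p in profiles)
    if n_ss > 1:
        raise TableValidationError(
            f"{n_ss} raters marked SS; exactly one senior surgeon is permitted"
        )
    return profiles


def write_plan_table(plans: PlanTable, path: str | Path) -> None:
    pd.DataFrame(
        [(r.rater_id, r.case_id, r.fragment_id, r.pose_ref) for r in plans.rows],
        columns=_PLAN_COLUMNS,
    ).to_csv(path, index=False)


def write_rater_table(profiles: Iterable[RaterProfile], path: str | Path) -> None:
    pd.DataFrame(
        [
            (
                p.rater_id,
                p.profession,
                "" if p.clinical_years is None else p.clinical_years,
                p.planning_years,
            )
            for p in profiles
        ],
        columns=_RATER_COLUMNS,
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Results I/O
# ---------------------------------------------------------------------------


def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_results(result, out_dir: str | Path) -> dict[str, Path]:
    """Write a StudyResult as ``study_result.json`` (full machine-readable
    record, numbers at full double precision) and ``rater_summaries.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / "study_result.json"
    json_path.write_text(json.dumps(_jsonify(result.to_dict()), indent=1))
    csv_path = out_dir / "rater_summaries.csv"
    pd.DataFrame(
        [
            {
                "rater_id": s.rater_id,
                "profession": s.profession,
                "mean_tfs_mm": s.mean_tfs,
                "sd_tfs_mm": s.sd_tfs,
                "mean_tfa_deg": s.mean_tfa,
                "sd_tfa_deg": s.sd_tfa,
                "n_cases": s.n_cases,
            }
            for s in result.rater_summaries
        ]
    ).to_csv(csv_path, index=False, float_format="%.17g")
    return {"json": json_path, "csv": csv_path}


def read_results(json_path: str | Path) -> dict:
    """Re-read the machine-readable study result written by write_results."""
    return json.loads(Path(json_path).read_text())
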