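"""The fragment displacement measure: transformation shift and angle.

The 3D displacement of a fragment between two poses is summarized by two
independent parameters:

* **TFS** (transformation shift, mm): length of the 3D displacement vector
  of the fragment center — the center of its minimal-volume oriented
  bounding box — between the two poses.
* **TFA** (transformation angle, degrees): rotation angle φ of the relative
  rigid motion, i.e. the pure rotational difference about the center.

TFS is computed by mapping the pose-1 center through the recovered relative
motion rather than by recomputing the bounding box in pose 2: the two are
mathematically identical for rigid motion, but mapping makes TFS exactly
invariant to bounding-box tie-breaking and floating-point orientation
jitter.  A diagnostic mode recomputes the pose-2 box and warns if the two
centers disagree beyond tolerance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import NonRigidInputError
from .geometry import compute_obb, horn_register, rotation_angle
from .mesh_io import RigidTransform, TriangleMesh

logger = logging.getLogger("fragdisp")

__all__ = ["DisplacementResult", "measure_displacement", "deviation_from_gold"]

#: relative tolerance (times mesh diameter) for the rigidity guard
RIGIDITY_RTOL = 1e-6

#: deterministic cap on vertices entering the pairwise-distance rigidity check
_RIGIDITY_MAX_VERTICES = 256


@dataclass(frozen=True)
class DisplacementResult:
    """TFS (mm) and TFA (degrees) of one fragment, with the registration RMS
    residual as a quality indicator (≈ 0 for exactly rigid input)."""

    tfs: float
    tfa: float
    fragment_id: str = ""
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        if self.tfs < 0:
            raise ValueError(f"tfs must be >= 0, got {self.tfs}")
        if not 0.0 <= self.tfa <= 180.0 + 1e-9:
            raise ValueError(f"tfa must be in [0, 180] degrees, got {self.tfa}")


def _rigidity_check(V1: np.ndarray, V2: np.ndarray, diameter: float) -> None:
    """Verify the two vertex sets are related by a rigid motion: all pairwise
    distances preserved within RIGIDITY_RTOL * diameter (evenly subsampled
    for large meshes)."""
    n = len(V1)
    if n > _RIGIDITY_MAX_VERTICES:
        idx = np.linspace(0, n - 1, _RIGIDITY_MAX_VERTICES).astype(int)
        V1, V2 = V1[idx], V2[idx]
    d1 = np.linalg.norm(V1[:, None, :] - V1[None, :, :], axis=-1)
    d2 = np.linalg.norm(V2[:, None, :] - V2[None, :, :], axis=-1)
    distortion = float(np.abs(d1 - d2).max())
    if distortion > RIGIDITY_RTOL * diameter:
        raise NonRigidInputError(
            f"vertex sets are not related by a rigid motion: max pairwise "
            f"distance distortion {distortion:.3e} mm exceeds "
            f"{RIGIDITY_RTOL:g} x diameter ({diameter:.3f} mm)"
        )


def displacement_between(
    V1: np.ndarray,
    V2: np.ndarray,
    center1: np.ndarray,
    *,
    fragment_id: str = "",
    diameter: float | None = None,
) -> tuple[DisplacementResult, RigidTransform]:
    """Core computation on already-posed vertex sets with a known pose-1
    center; returns the result and the recovered relative motion."""
    V1 = np.asarray(V1, dtype=float)
    V2 = np.asarray(V2, dtype=float)
    if diameter is None:
        diameter = float(np.linalg.norm(np.ptp(V1, axis=0)))
    _rigidity_check(V1, V2, diameter)
    reg = horn_register(V1, V2)
    c1 = np.asarray(center1, dtype=float)
    c2 = reg.transform.apply(c1)
    tfs = float(np.linalg.norm(c2 - c1))
    tfa = rotation_angle(reg.transform.quaternion)
    return (
        DisplacementResult(tfs, tfa, fragment_id, reg.rms_residual),
        reg.transform,
    )


def measure_displacement(
    mesh: TriangleMesh,
    pose1: RigidTransform,
    pose2: RigidTransform,
    *,
    diagnostics: bool = False,
) -> DisplacementResult:
    """TFS and TFA of ``mesh`` moving from ``pose1`` (pre-reduction) to
    ``pose2`` (post-reduction).

    The relative motion ``M = pose2 ∘ pose1⁻¹`` is recovered by Horn
    registration of the posed vertex sets; TFS is the displacement of the
    pose-1 bounding-box center through M, TFA the rotation angle of M.

    With ``diagnostics=True`` the bounding box is additionally recomputed in
    pose 2 and a warning is emitted if its center differs from the mapped
    center by more than 1e-6 times the mesh diameter.
    """
    V1 = pose1.apply(mesh.vertices)
    V2 = pose2.apply(mesh.vertices)
    c1 = compute_obb(V1).center
    result, motion = displacement_between(
        V1, V2, c1, fragment_id=mesh.name, diameter=mesh.diameter
    )
    if diagnostics:
        c2_direct = compute_obb(V2).center
        gap = float(np.linalg.norm(c2_direct - motion.apply(c1)))
        if gap > 1e-6 * mesh.diameter:
            warnings.warn(
                f"fragment {mesh.name!r}: pose-2 OBB center differs from the "
                f"mapped pose-1 center by {gap:.3e} mm",
                stacklevel=2,
            )
    return result


def deviation_from_gold(
    mesh: TriangleMesh,
    pose_rater: RigidTransform,
    pose_gold: RigidTransform,
) -> DisplacementResult:
    """Deviation of a rater's final fragment pose from the gold-standard
    final pose: ``measure_displacement(mesh, pose_gold, pose_rater)``."""
    return measure_displacement(mesh, pose_gold, pose_rater)
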