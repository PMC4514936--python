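"""Rigid pose differences between planned and post-operative fiducial triads.

The translational difference of a region is the vector between the planned
and post-operative barycenters.  The rotational difference is the proper
rotation that best aligns the planned barycenter-to-screw vectors onto the
post-operative ones in the least-squares sense (orthogonal Procrustes /
Kabsch, reflections excluded), reported as pitch / roll / yaw:

* pitch — rotation about the medio-lateral x axis,
* roll  — rotation about the antero-posterior y axis,
* yaw   — rotation about the supero-inferior z axis.

Two angle conventions are provided.  ``standard`` (the default) is a full
Euler decomposition of the estimated rotation matrix, sequence z-y-x with the
yaw factor applied first (R = Rx(pitch) @ Ry(roll) @ Rz(yaw)); it is zero at
the identity and well defined for every rotation outside gimbal lock
(|roll| -> 90 deg, flagged).  ``paper_literal`` evaluates the two-argument
arctangent formulas of the original cadaver study verbatim on the rotated +y
axis; it is kept for traceability only — it cannot encode rotation about y
and its yaw formula returns 90 deg at the identity.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import (
    FiducialTriad,
    Region,
    Timepoint,
    VectorTriad,
    barycenter,
    vector_triad,
)

__all__ = [
    "AngleConvention",
    "TranslationDifference",
    "RotationEstimate",
    "RotationDifference",
    "PoseDifference",
    "RegionMismatchError",
    "translation_difference",
    "estimate_rotation",
    "rotation_angles",
    "pose_difference",
    "euler_to_matrix",
    "matrix_to_euler",
]

#: Euler sequence used throughout: extrinsic z-y-x, i.e. the rotation factors
#: as R = Rx(pitch) @ Ry(roll) @ Rz(yaw), yaw applied first.  At the small
#: angles of surgical repositioning the sequence choice is second order.
_EULER_SEQ = "zyx"

_GIMBAL_TOL = 1e-8


class AngleConvention(str, enum.Enum):
    STANDARD = "standard"
    PAPER_LITERAL = "paper_literal"


class RegionMismatchError(ValueError):
    """Raised when an operation pairs triads of different regions."""


@dataclass(frozen=True)
class TranslationDifference:
    """Post-operative minus planned barycenter, components in mm."""

    region: Region
    dx: float
    dy: float
    dz: float
    magnitude: float

    @property
    def components(self) -> np.ndarray:
        return np.array([self.dx, self.dy, self.dz])


@dataclass(frozen=True)
class RotationEstimate:
    """Least-squares proper rotation mapping planned onto post-op vectors."""

    region: Region
    matrix: np.ndarray  # 3x3 proper orthogonal
    transformed_y_axis: np.ndarray  # image of (0, 1, 0) under the rotation
    residual_rmse: float  # mm, per-vector RMS misfit after rotation

    def __post_init__(self) -> None:
        R = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", R)
        object.__setattr__(
            self, "transformed_y_axis", np.asarray(self.transformed_y_axis, float)
        )
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation matrix is not proper (det != +1)")


@dataclass(frozen=True)
class RotationDifference:
    """Pitch / roll / yaw in degrees, each in (-180, 180]."""

    region: Region
    pitch: float
    roll: float
    yaw: float
    convention: AngleConvention
    gimbal_lock: bool = False

    @property
    def angles(self) -> np.ndarray:
        return np.array([self.pitch, self.roll, self.yaw])


@dataclass(frozen=True)
class PoseDifference:
    """Full planned-to-post-operative pose difference of one region."""

    region: Region
    translation: TranslationDifference
    rotation: RotationDifference
    rotation_estimate: RotationEstimate


def _require_pair(plan: FiducialTriad, post: FiducialTriad) -> None:
    if plan.region != post.region:
        raise RegionMismatchError(
            f"cannot compare regions {plan.region.value!r} and {post.region.value!r}"
        )
    if plan.timepoint != Timepoint.PLANNED or post.timepoint != Timepoint.POSTOP:
        raise ValueError(
            f"{plan.region.value}: expected (planned, postop) pair, got "
            f"({plan.timepoint.value}, {post.timepoint.value})"
        )
    if plan.labels != post.labels:
        from .geometry import LabelMismatchError

        raise LabelMismatchError(
            f"{plan.region.value}: screw labels differ between timepoints "
            f"({plan.labels} vs {post.labels})"
        )


def translation_difference(
    plan: FiducialTriad, post: FiducialTriad
) -> TranslationDifference:
    """Barycenter displacement (post-op minus planned) of one region."""
    _require_pair(plan, post)
    d = barycenter(post).point.as_array() - barycenter(plan).point.as_array()
    return TranslationDifference(
        plan.region, float(d[0]), float(d[1]), float(d[2]),
        float(np.linalg.norm(d)),
    )


def estimate_rotation(
    plan_vectors: VectorTriad, post_vectors: VectorTriad
) -> RotationEstimate:
    """Least-squares proper rotation aligning planned onto post-op vectors.

    Solves the orthogonal Procrustes problem min_R sum_i |R v_plan,i -
    v_ppop,i|^2 over proper rotations (Kabsch).  The residual RMSE is the
    per-vector RMS misfit after applying the optimal rotation; it is zero
    exactly when the motion was rigid.
    """
    if Region(plan_vectors.region) != Region(post_vectors.region):
        raise RegionMismatchError(
            f"cannot align vector triads of regions "
            f"{Region(plan_vectors.region).value!r} and "
            f"{Region(post_vectors.region).value!r}"
        )
    rot, _ = Rotation.align_vectors(post_vectors.vectors, plan_vectors.vectors)
    R = rot.as_matrix()
    misfit = plan_vectors.vectors @ R.T - post_vectors.vectors
    return RotationEstimate(
        region=Region(plan_vectors.region),
        matrix=R,
        transformed_y_axis=R @ np.array([0.0, 1.0, 0.0]),
        residual_rmse=float(np.sqrt((misfit**2).sum() / 3.0)),
    )


def euler_to_matrix(pitch: float, roll: float, yaw: float) -> np.ndarray:
    """Rotation matrix for pitch/roll/yaw degrees in the package convention."""
    return Rotation.from_euler(
        _EULER_SEQ, [yaw, roll, pitch], degrees=True
    ).as_matrix()


def matrix_to_euler(R: np.ndarray) -> tuple[float, float, float]:
    """(pitch, roll, yaw) degrees of a rotation matrix, package convention."""
    import warnings

    with warnings.catch_warnings():
        # gimbal lock is detected and flagged separately by rotation_angles
        warnings.filterwarnings("ignore", message="Gimbal lock detected")
        yaw, roll, pitch = Rotation.from_matrix(np.asarray(R, float)).as_euler(
            _EULER_SEQ, degrees=True
        )
    return float(pitch), float(roll), float(yaw)


def rotation_angles(
    est: RotationEstimate,
    convention: AngleConvention | str = AngleConvention.STANDARD,
) -> RotationDifference:
    """Extract pitch / roll / yaw (degrees) from a rotation estimate.

    ``standard`` decomposes the full rotation matrix; gimbal lock
    (|roll| -> 90 deg) is flagged but the angles are still returned — at
    surgical magnitudes the flag marks corrupt input, not a real pose.
    ``paper_literal`` applies the printed single-axis arctangent formulas to
    the rotated +y axis.
    """
    convention = AngleConvention(convention)
    R = est.matrix
    if convention is AngleConvention.STANDARD:
        pitch, roll, yaw = matrix_to_euler(R)
        # sin(roll) sits at R[0, 2] in the Rx @ Ry @ Rz factorisation
        gimbal = bool(abs(abs(float(R[0, 2])) - 1.0) < _GIMBAL_TOL)
        return RotationDifference(est.region, pitch, roll, yaw, convention, gimbal)
    yx, yy, yz = est.transformed_y_axis
    return RotationDifference(
        region=est.region,
        pitch=float(np.degrees(np.arctan2(yz, yy))),
        roll=float(np.degrees(np.arctan2(yx, yy))),
        yaw=float(np.degrees(np.arctan2(yy, yx))),
        convention=convention,
        gimbal_lock=False,
    )


def pose_difference(
    plan: FiducialTriad,
    post: FiducialTriad,
    convention: AngleConvention | str = AngleConvention.STANDARD,
) -> PoseDifference:
    """Translation + rotation difference between a planned/post-op triad pair."""
    _require_pair(plan, post)
    trans = translation_difference(plan, post)
    est = estimate_rotation(vector_triad(plan), vector_triad(post))
    return PoseDifference(plan.region, trans, rotation_angles(est, convention), est)
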