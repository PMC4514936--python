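"""Decomposition of maxillary repositioning error and screw deformation.

During surgery the maxilla is wired to the mandible through the occlusal
splint, so the measured maxillary repositioning error (MxRE) is the sum of
the mandibular (condylar) repositioning error (MdRE) and the intrinsic
splint error (SE):

    MxRE = MdRE + SE     per specimen and per component,

hence SE = MxRE - MdRE, computed specimen-wise on the signed translation
components and angles *before* any aggregation.  (Subtracting aggregate
RMSDs instead is not equivalent and is not done here.)

Screw deformation is quantified as the non-rigid remainder of each triad's
motion: after the best-fit rigid transform (Kabsch rotation about the
barycenter plus barycenter translation) is applied to the planned triad, the
per-screw, per-axis residuals against the post-operative triad are the
fiducial deformation; their RMSD across screws and specimens gives the
per-region, per-axis deformation table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import FiducialTriad, Region, barycenter, vector_triad
from .pose import RegionMismatchError, estimate_rotation, matrix_to_euler

__all__ = [
    "COMPONENTS",
    "TRANSLATION_COMPONENTS",
    "ROTATION_COMPONENTS",
    "RegionErrorSeries",
    "SplintErrorSeries",
    "splint_error",
    "splint_rotation_exact",
    "ipd_deformation",
    "ipd_fraction",
]

TRANSLATION_COMPONENTS = ("dx_mm", "dy_mm", "dz_mm")
ROTATION_COMPONENTS = ("pitch_deg", "roll_deg", "yaw_deg")
COMPONENTS = TRANSLATION_COMPONENTS + ROTATION_COMPONENTS


@dataclass(frozen=True)
class RegionErrorSeries:
    """Signed pose-difference components per specimen for one region.

    ``frame`` is indexed by specimen id with the six component columns
    (three translations in mm, three angles in degrees).
    """

    region: Region
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COMPONENTS if c not in self.frame.columns]
        if missing:
            raise ValueError(
                f"{Region(self.region).value}: error series missing columns {missing}"
            )
        object.__setattr__(
            self, "frame", self.frame.loc[:, list(COMPONENTS)].astype(float)
        )


@dataclass(frozen=True)
class SplintErrorSeries:
    """Per-specimen splint error SE = MxRE - MdRE, component-wise."""

    frame: pd.DataFrame


def splint_error(
    maxilla: RegionErrorSeries, mandible: RegionErrorSeries
) -> SplintErrorSeries:
    """Specimen-wise, component-wise SE = maxilla error - mandible error."""
    if Region(maxilla.region) != Region.MAXILLA:
        raise ValueError(f"first argument must be the maxilla series, got "
                         f"{Region(maxilla.region).value}")
    if Region(mandible.region) != Region.MANDIBLE:
        raise ValueError(f"second argument must be the mandible series, got "
                         f"{Region(mandible.region).value}")
    if not maxilla.frame.index.equals(mandible.frame.index):
        raise ValueError(
            "maxilla and mandible error series index different specimens: "
            f"{list(maxilla.frame.index)} vs {list(mandible.frame.index)}"
        )
    return SplintErrorSeries(maxilla.frame - mandible.frame)


def splint_rotation_exact(
    maxilla_rotation: np.ndarray, mandible_rotation: np.ndarray
) -> tuple[float, float, float]:
    """Splint rotation as exact relative rotation R_mx @ R_md^T, in Euler angles.

    The per-component angle subtraction used by ``splint_error`` is the
    small-angle approximation of this composition; the discrepancy is second
    order in the angles (below ~0.1 deg when each rotation stays within a few
    degrees, growing to ~0.5 deg near 10 deg).
    """
    rel = np.asarray(maxilla_rotation, float) @ np.asarray(mandible_rotation, float).T
    return matrix_to_euler(rel)


def ipd_deformation(plan: FiducialTriad, post: FiducialTriad) -> np.ndarray:
    """Per-screw, per-axis non-rigid residuals (mm) after the best-fit rigid
    transform of the planned triad onto the post-operative one.

    Returns a 3x3 array (screws x axes).  Exactly zero for a rigid motion;
    non-zero entries localise screw deformation per axis, feeding the
    deformation RMSD table.
    """
    if plan.region != post.region:
        raise RegionMismatchError(
            f"cannot compute deformation across regions "
            f"{plan.region.value!r} and {post.region.value!r}"
        )
    est = estimate_rotation(vector_triad(plan), vector_triad(post))
    b_plan = barycenter(plan).point.as_array()
    b_post = barycenter(post).point.as_array()
    fitted = (plan.coords - b_plan) @ est.matrix.T + b_post
    return post.coords - fitted


def ipd_fraction(ipd_rmsd: float, overall_rmsd: float) -> float:
    """Deformation RMSD as a percentage of the overall RMSD on the same axis."""
    if overall_rmsd <= 0:
        raise ValueError(f"overall RMSD must be positive, got {overall_rmsd}")
    if ipd_rmsd < 0:
        raise ValueError(f"deformation RMSD cannot be negative, got {ipd_rmsd}")
    return 100.0 * ipd_rmsd / overall_rmsd
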