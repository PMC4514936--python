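"""Fiducial landmark containers and basic triad geometry.

The measurement unit of the whole pipeline is a *fiducial triad*: three
labeled bone screws of one anatomical region (skull, maxilla or mandible)
observed at one timepoint (planned or post-operative).  All coordinates are
millimetres in a right-handed frame with

* ``x``: medio-lateral axis (positive toward the specimen's left),
* ``y``: antero-posterior axis (positive anterior),
* ``z``: supero-inferior axis (positive superior).

The barycenter of a triad (component-wise mean of the three screws) is the
region's rigid-body reference landmark; the vectors from the barycenter to
each screw span the region's orientation and feed the rotation estimate.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Region",
    "Timepoint",
    "Point3D",
    "FiducialTriad",
    "Barycenter",
    "VectorTriad",
    "DegenerateTriadError",
    "LabelMismatchError",
    "barycenter",
    "vector_triad",
    "inter_point_distances",
    "triangle_area",
    "DEFAULT_AREA_EPS_MM2",
]

#: Minimum triangle area (mm^2) below which a triad is treated as collinear.
#: 1.5 mm screws placed centimetres apart never form a genuinely flat triad;
#: a near-zero area indicates a data-entry or detection error.
DEFAULT_AREA_EPS_MM2 = 1.0


class Region(str, enum.Enum):
    """Anatomical region carrying one fiducial triad."""

    SKULL = "skull"
    MAXILLA = "maxilla"
    MANDIBLE = "mandible"


class Timepoint(str, enum.Enum):
    """Observation timepoint: virtual plan or post-operative CT."""

    PLANNED = "planned"
    POSTOP = "postop"


class DegenerateTriadError(ValueError):
    """Raised when a triad's screws are (near-)collinear or non-finite."""


class LabelMismatchError(ValueError):
    """Raised when two triads that must share screw labels do not."""


@dataclass(frozen=True)
class Point3D:
    """A single screw position in mm: x medio-lateral, y antero-posterior,
    z supero-inferior."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for c in (self.x, self.y, self.z):
            if not math.isfinite(c):
                raise ValueError(f"non-finite coordinate in {self!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, a) -> "Point3D":
        a = np.asarray(a, dtype=float)
        return cls(float(a[0]), float(a[1]), float(a[2]))


def triangle_area(coords: np.ndarray) -> float:
    """Area (mm^2) of the triangle spanned by three stacked 3D points."""
    a, b, c = np.asarray(coords, dtype=float)
    return 0.5 * float(np.linalg.norm(np.cross(b - a, c - a)))


@dataclass(frozen=True)
class FiducialTriad:
    """Three labeled screws of one region at one timepoint.

    ``points`` maps screw labels 1..3 to positions.  Labels are stable across
    timepoints: label *k* at the planned timepoint is the same physical screw
    as label *k* post-operatively.  A triad whose screws are collinear within
    ``area_eps`` (triangle area, mm^2) is rejected at construction.
    """

    region: Region
    timepoint: Timepoint
    points: tuple[Point3D, Point3D, Point3D]
    labels: tuple[int, int, int] = (1, 2, 3)
    area_eps: float = field(default=DEFAULT_AREA_EPS_MM2, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "region", Region(self.region))
        object.__setattr__(self, "timepoint", Timepoint(self.timepoint))
        if len(self.points) != 3:
            raise ValueError(
                f"{self.region.value}/{self.timepoint.value}: a triad needs "
                f"exactly 3 points, got {len(self.points)}"
            )
        if len(set(self.labels)) != 3:
            raise ValueError(
                f"{self.region.value}/{self.timepoint.value}: screw labels "
                f"must be unique, got {self.labels}"
            )
        area = triangle_area(self.coords)
        if area <= self.area_eps:
            raise DegenerateTriadError(
                f"degenerate fiducial triad for region={self.region.value} "
                f"timepoint={self.timepoint.value}: triangle area "
                f"{area:.6g} mm^2 <= {self.area_eps:g} mm^2 (collinear screws)"
            )

    @property
    def coords(self) -> np.ndarray:
        """3x3 array, one screw per row, ordered by label."""
        order = np.argsort(self.labels)
        pts = np.stack([self.points[i].as_array() for i in order])
        return pts

    @classmethod
    def from_coords(
        cls,
        region: Region | str,
        timepoint: Timepoint | str,
        coords,
        labels: tuple[int, int, int] = (1, 2, 3),
        area_eps: float = DEFAULT_AREA_EPS_MM2,
    ) -> "FiducialTriad":
        coords = np.asarray(coords, dtype=float)
        pts = tuple(Point3D.from_array(row) for row in coords)
        return cls(Region(region), Timepoint(timepoint), pts, labels, area_eps)

    def translated(self, t) -> "FiducialTriad":
        """The same triad rigidly shifted by vector ``t`` (mm)."""
        return FiducialTriad.from_coords(
            self.region, self.timepoint, self.coords + np.asarray(t, float),
            area_eps=self.area_eps,
        )

    def transformed(self, rotation: np.ndarray, translation) -> "FiducialTriad":
        """Apply a rigid transform ``p -> R p + t`` to every screw."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return FiducialTriad.from_coords(
            self.region, self.timepoint, self.coords @ R.T + t,
            area_eps=self.area_eps,
        )


@dataclass(frozen=True)
class Barycenter:
    """Component-wise mean of a triad's three screws (the region landmark)."""

    region: Region
    timepoint: Timepoint
    point: Point3D


@dataclass(frozen=True)
class VectorTriad:
    """Vectors from the barycenter to each screw, labelled like the screws.

    By construction the three vectors sum to the zero vector, so they carry
    the orientation (not the position) of the region.
    """

    region: Region
    timepoint: Timepoint
    vectors: np.ndarray  # 3x3, one vector per row, ordered by label

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        object.__setattr__(self, "vectors", v)
        if v.shape != (3, 3):
            raise ValueError(f"expected 3x3 vector triad, got {v.shape}")
        if not np.allclose(v.sum(axis=0), 0.0, atol=1e-9):
            raise ValueError(
                f"{Region(self.region).value}/{Timepoint(self.timepoint).value}: "
                "barycenter-relative vectors must sum to zero"
            )


def barycenter(triad: FiducialTriad) -> Barycenter:
    """Barycenter of a triad: the arithmetic mean of its three screws."""
    mean = triad.coords.mean(axis=0)
    return Barycenter(triad.region, triad.timepoint, Point3D.from_array(mean))


def vector_triad(triad: FiducialTriad) -> VectorTriad:
    """Vectors barycenter -> screw for each of the three screws."""
    coords = triad.coords
    return VectorTriad(triad.region, triad.timepoint, coords - coords.mean(axis=0))


def inter_point_distances(triad: FiducialTriad) -> tuple[float, float, float]:
    """Pairwise Euclidean screw distances (mm) for pairs (1,2), (1,3), (2,3).

    Invariant under any rigid transform of the triad; changes only when the
    screws themselves move relative to the bone (deformation).
    """
    p = triad.coords
    return (
        float(np.linalg.norm(p[0] - p[1])),
        float(np.linalg.norm(p[0] - p[2])),
        float(np.linalg.norm(p[1] - p[2])),
    )
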