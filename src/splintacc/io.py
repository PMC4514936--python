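"""Landmark file formats.

The landmark table has one row per screw observation:

    head_id, timepoint, region, screw_label, x_mm, y_mm, z_mm

with ``timepoint`` in {planned, postop}, ``region`` in {skull, maxilla,
mandible} and ``screw_label`` in {1, 2, 3}.  CSV (UTF-8, decimal point,
header required) and an equivalent nested JSON layout are supported; writers
emit fixed 6-decimal coordinates so that a write -> read round trip is
lossless and two writes of the same study are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .geometry import FiducialTriad, Point3D, Region, Timepoint
from .study import SpecimenSet

__all__ = ["LANDMARK_COLUMNS", "read_landmarks", "write_landmarks",
           "specimen_set_to_frame", "LandmarkFormatError"]

LANDMARK_COLUMNS = (
    "head_id", "timepoint", "region", "screw_label", "x_mm", "y_mm", "z_mm"
)

_COORD_FMT = "{:.6f}"


class LandmarkFormatError(ValueError):
    """Raised for schema violations in a landmark file."""


def specimen_set_to_frame(specimen_set: SpecimenSet) -> pd.DataFrame:
    """Flatten a specimen set into the landmark table (sorted, one row per
    screw observation)."""
    rows = []
    for (head, region, timepoint), triad in specimen_set.triads.items():
        coords = triad.coords
        for label, row in zip(sorted(triad.labels), coords):
            rows.append(
                (head, timepoint.value, region.value, int(label),
                 float(row[0]), float(row[1]), float(row[2]))
            )
    frame = pd.DataFrame(rows, columns=list(LANDMARK_COLUMNS))
    return frame.sort_values(
        ["head_id", "timepoint", "region", "screw_label"], kind="mergesort"
    ).reset_index(drop=True)


def _frame_to_specimen_set(frame: pd.DataFrame, source: str) -> SpecimenSet:
    missing = [c for c in LANDMARK_COLUMNS if c not in frame.columns]
    if missing:
        raise LandmarkFormatError(f"{source}: missing columns {missing}")

    frame = frame.copy()
    frame["screw_label"] = pd.to_numeric(frame["screw_label"], errors="coerce")
    for i, row in frame.iterrows():
        rowno = i + 2  # 1-based with header line
        if row["timepoint"] not in {t.value for t in Timepoint}:
            raise LandmarkFormatError(
                f"{source}, row {rowno}: unknown timepoint {row['timepoint']!r}"
            )
        if row["region"] not in {r.value for r in Region}:
            raise LandmarkFormatError(
                f"{source}, row {rowno}: unknown region {row['region']!r}"
            )
        if row["screw_label"] not in (1, 2, 3):
            raise LandmarkFormatError(
                f"{source}, row {rowno}: screw_label must be 1, 2 or 3, "
                f"got {row['screw_label']!r}"
            )

    dupes = frame.duplicated(
        subset=["head_id", "timepoint", "region", "screw_label"], keep=False
    )
    if dupes.any():
        bad = frame.loc[dupes, ["head_id", "timepoint", "region", "screw_label"]]
        raise LandmarkFormatError(
            f"{source}: duplicate screw observations at rows "
            f"{[int(i) + 2 for i in bad.index]}"
        )

    specimen_set = SpecimenSet()
    grouped = frame.groupby(["head_id", "timepoint", "region"], sort=True)
    for (head, timepoint, region), group in grouped:
        if len(group) != 3:
            raise LandmarkFormatError(
                f"{source}: head={head} region={region} timepoint={timepoint} "
                f"has {len(group)} screws, expected 3 "
                f"(labels {sorted(group['screw_label'].tolist())})"
            )
        group = group.sort_values("screw_label")
        points = tuple(
            Point3D(float(r.x_mm), float(r.y_mm), float(r.z_mm))
            for r in group.itertuples()
        )
        triad = FiducialTriad(
            Region(region), Timepoint(timepoint), points,
            labels=tuple(int(v) for v in group["screw_label"]),
        )
        specimen_set.add(str(head), triad)
    return specimen_set


def read_landmarks(path: str | Path) -> SpecimenSet:
    """Read a landmark CSV or JSON file into a validated specimen set."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _read_landmarks_json(path)
    frame = pd.read_csv(path, dtype={"head_id": str})
    return _frame_to_specimen_set(frame, str(path))


def write_landmarks(specimen_set: SpecimenSet, path: str | Path) -> None:
    """Write a specimen set as landmark CSV or JSON (6-decimal coordinates)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        _write_landmarks_json(specimen_set, path)
        return
    frame = specimen_set_to_frame(specimen_set)
    out = frame.copy()
    for c in ("x_mm", "y_mm", "z_mm"):
        out[c] = out[c].map(_COORD_FMT.format)
    out.to_csv(path, index=False, lineterminator="\n")


def _write_landmarks_json(specimen_set: SpecimenSet, path: Path) -> None:
    frame = specimen_set_to_frame(specimen_set)
    payload: dict = {}
    for row in frame.itertuples():
        head = payload.setdefault(row.head_id, {})
        tp = head.setdefault(row.timepoint, {})
        region = tp.setdefault(row.region, {})
        region[str(row.screw_label)] = [
            float(_COORD_FMT.format(v)) for v in (row.x_mm, row.y_mm, row.z_mm)
        ]
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _read_landmarks_json(path: Path) -> SpecimenSet:
    payload = json.loads(path.read_text())
    rows = []
    for head, timepoints in payload.items():
        for timepoint, regions in timepoints.items():
            for region, screws in regions.items():
                for label, xyz in screws.items():
                    if len(xyz) != 3:
                        raise LandmarkFormatError(
                            f"{path}: head={head} region={region} screw={label} "
                            f"has {len(xyz)} coordinates, expected 3"
                        )
                    rows.append(
                        (head, timepoint, region, int(label), *map(float, xyz))
                    )
    frame = pd.DataFrame(rows, columns=list(LANDMARK_COLUMNS))
    return _frame_to_specimen_set(frame, str(path))
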