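"""Slice contour containers and CSV round-tripping.

A cross-section of a coronary vessel is represented by a set of closed
planar polygons (coordinates in mm, counterclockwise): the lumen boundary,
the vessel outwall, and optionally a lipid core and a calcification.  Each
polygon is tagged with patient, slice, timepoint (baseline/follow-up) and
modality (IO = fused IVUS+OCT, or IVUS-only).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

TIMEPOINTS = ("baseline", "follow_up")
MODALITIES = ("IO", "IVUS")
ROLES = ("lumen", "outwall", "lipid", "calcification")

CONTOUR_COLUMNS = [
    "patient_id",
    "slice_id",
    "timepoint",
    "modality",
    "role",
    "point_index",
    "x_mm",
    "y_mm",
]


@dataclass
class SliceContour:
    """One closed planar polygon with a tissue role.

    ``points`` is an (n, 2) array in mm; the polygon is implicitly closed
    (last vertex connects back to the first) and oriented counterclockwise.
    """

    patient_id: str
    slice_id: str
    timepoint: str
    modality: str
    role: str
    points: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.points)

    def is_valid(self, min_vertices: int = 24) -> bool:
        """Simple (non-self-intersecting) closed polygon with enough vertices."""
        return len(self.points) >= min_vertices and self.polygon.is_valid

    def with_points(self, points: np.ndarray) -> "SliceContour":
        return replace(self, points=np.asarray(points, dtype=float))


# A contour set: all polygons of one (patient, slice, timepoint, modality),
# keyed by role.  The lumen and outwall are mandatory downstream.
ContourSet = dict


def validate_contour_set(cs: ContourSet) -> None:
    """Check the geometric invariants of a slice contour set.

    Every polygon must be simple with >= 24 vertices; the lumen must lie
    strictly inside the outwall; any lipid must lie inside the wall annulus
    (inside the outwall, outside the open lumen).
    """
    for role, contour in cs.items():
        if not contour.is_valid():
            raise ValueError(f"{role} contour invalid (self-intersecting or too few vertices)")
    lumen = cs["lumen"].polygon
    outwall = cs["outwall"].polygon
    if not outwall.contains(lumen):
        raise ValueError("lumen is not strictly inside the outwall")
    if "lipid" in cs:
        lipid = cs["lipid"].polygon
        annulus = outwall.difference(lumen)
        if not annulus.buffer(1e-9).contains(lipid):
            raise ValueError("lipid is not inside the wall annulus")


def contour_sets_to_frame(sets: Iterable[ContourSet]) -> pd.DataFrame:
    """Flatten contour sets into the one-row-per-vertex CSV layout."""
    rows = []
    for cs in sets:
        for contour in cs.values():
            n = len(contour.points)
            rows.append(
                pd.DataFrame(
                    {
                        "patient_id": contour.patient_id,
                        "slice_id": contour.slice_id,
                        "timepoint": contour.timepoint,
                        "modality": contour.modality,
                        "role": contour.role,
                        "point_index": np.arange(n),
                        "x_mm": contour.points[:, 0],
                        "y_mm": contour.points[:, 1],
                    }
                )
            )
    if not rows:
        return pd.DataFrame(columns=CONTOUR_COLUMNS)
    return pd.concat(rows, ignore_index=True)[CONTOUR_COLUMNS]


def frame_to_contour_sets(df: pd.DataFrame) -> list[ContourSet]:
    """Rebuild contour sets from the vertex table, grouped by slice identity."""
    sets = []
    keys = ["patient_id", "slice_id", "timepoint", "modality"]
    for _, group in df.groupby(keys, sort=True):
        cs: ContourSet = {}
        for role, sub in group.groupby("role", sort=True):
            sub = sub.sort_values("point_index")
            first = sub.iloc[0]
            cs[role] = SliceContour(
                patient_id=str(first["patient_id"]),
                slice_id=str(first["slice_id"]),
                timepoint=str(first["timepoint"]),
                modality=str(first["modality"]),
                role=str(role),
                points=sub[["x_mm", "y_mm"]].to_numpy(),
            )
        sets.append(cs)
    return sets


def save_contours(sets: Iterable[ContourSet], path: str | Path) -> None:
    contour_sets_to_frame(sets).to_csv(path, index=False, float_format="%.6f")


def load_contours(path: str | Path) -> list[ContourSet]:
    return frame_to_contour_sets(pd.read_csv(path, dtype={"patient_id": str, "slice_id": str}))
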