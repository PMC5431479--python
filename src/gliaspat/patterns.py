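"""Marked spatial point patterns in a polygonal observation window.

Coordinate convention (used everywhere in this package): distances in μm,
origin at the top-left of the window bounding box, y increasing downward
(image convention). Areas are μm² internally; densities are reported in
cells/mm², the field's customary unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon

UM2_PER_MM2 = 1e6

#: the two activity phenotypes carried as point marks
MARK_LOW = "low"
MARK_HIGH = "high"


@dataclass
class PointPattern:
    """A (possibly marked) point pattern observed in a polygonal window.

    Parameters
    ----------
    points : (n, 2) float array
        Cell centroids in μm, columns (x, y).
    window : shapely.geometry.Polygon
        Observation window (retinal boundary) in μm.
    marks : (n,) object array, optional
        Per-point activity label, ``"low"`` or ``"high"``.
    retina_id : str
        Identifier of the source retina.
    group : str
        Treatment group; the study vocabulary is {naive, onc, co_eye} but
        arbitrary labels are accepted.
    """

    points: np.ndarray
    window: Polygon
    marks: np.ndarray | None = None
    retina_id: str = "retina"
    group: str = "naive"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.marks is not None:
            self.marks = np.asarray(self.marks, dtype=object)
            if len(self.marks) != len(self.points):
                raise ValueError(
                    f"marks length {len(self.marks)} != points length {len(self.points)}"
                )
        if not self.window.is_valid or self.window.area <= 0:
            raise ValueError("window polygon is invalid or has zero area")

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def area_um2(self) -> float:
        return float(self.window.area)

    @property
    def area_mm2(self) -> float:
        return self.area_um2 / UM2_PER_MM2

    @property
    def intensity_per_mm2(self) -> float:
        """Empirical intensity n / |W| in cells/mm²."""
        return self.n / self.area_mm2

    def subset(self, mask: np.ndarray) -> "PointPattern":
        """Pattern restricted to ``mask`` (bool or index array); window kept."""
        marks = self.marks[mask] if self.marks is not None else None
        return PointPattern(
            self.points[mask], self.window, marks, self.retina_id, self.group
        )

    def split_by_mark(self) -> dict[str, "PointPattern"]:
        """One unmarked sub-pattern per distinct mark value."""
        if self.marks is None:
            raise ValueError("pattern has no marks")
        out = {}
        for m in sorted(set(self.marks)):
            sub = self.subset(self.marks == m)
            sub.marks = None
            out[str(m)] = sub
        return out

    def contains_all(self) -> bool:
        """True when every point lies inside (or on) the window."""
        x, y = self.points[:, 0], self.points[:, 1]
        return bool(np.all(shapely.intersects_xy(self.window, x, y)))


def rectangle_window(width_um: float, height_um: float) -> Polygon:
    """Axis-aligned rectangular window with origin at the top-left corner."""
    return Polygon(
        [(0, 0), (width_um, 0), (width_um, height_um), (0, height_um)]
    )


def is_axis_aligned_rectangle(window: Polygon, rtol: float = 1e-9) -> bool:
    """True when the window fills its own axis-aligned bounding box."""
    minx, miny, maxx, maxy = window.bounds
    bbox_area = (maxx - minx) * (maxy - miny)
    return bbox_area > 0 and abs(window.area - bbox_area) <= rtol * bbox_area
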