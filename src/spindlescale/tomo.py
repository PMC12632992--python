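"""End-point classification of traced spindle microtubules.

Electron-tomography traces are classified by geometry: a microtubule with
either end within ``pole_radius`` of a centriole is *interpolar*; one with
both ends strictly inside the open slab bounded by the two chromosome
plate planes (and neither end pole-proximal) is *mid-spindle*; everything
else is *other*. Interpolar takes precedence when both predicates hold.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import GeometryError

__all__ = [
    "MTTrace",
    "SpindleGeometry",
    "classify_microtubule",
    "summarize_population",
    "DEFAULT_POLE_RADIUS",
]

DEFAULT_POLE_RADIUS = 0.5  # um; "near a centriole" threshold
CLASSES = ("interpolar", "mid_spindle", "other")


@dataclass(frozen=True)
class MTTrace:
    """Ordered 3D polyline of one traced microtubule (um)."""

    points: np.ndarray
    trace_id: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValueError("a trace needs at least 2 points of shape (n, 3)")
        if not np.all(np.isfinite(pts)):
            raise ValueError("trace coordinates must be finite")
        object.__setattr__(self, "points", pts)

    @property
    def ends(self) -> tuple[np.ndarray, np.ndarray]:
        return self.points[0], self.points[-1]


@dataclass(frozen=True)
class SpindleGeometry:
    """Centrioles plus the two chromosome-plate planes.

    Both planes share the spindle-axis normal; each is anchored at its
    plate centroid.
    """

    centriole1: np.ndarray
    centriole2: np.ndarray
    plate1_centroid: np.ndarray
    plate2_centroid: np.ndarray
    axis: np.ndarray  # shared plane normal; normalised on construction

    def __post_init__(self) -> None:
        for name in ("centriole1", "centriole2", "plate1_centroid", "plate2_centroid", "axis"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        norm = np.linalg.norm(self.axis)
        if norm == 0:
            raise GeometryError("spindle axis must be non-zero")
        object.__setattr__(self, "axis", self.axis / norm)
        gap = (self.plate1_centroid - self.plate2_centroid) @ self.axis
        if abs(gap) < 1e-9:
            raise GeometryError("chromosome plates coincide along the axis: empty mid-spindle region")


def _between_plates(point: np.ndarray, geom: SpindleGeometry) -> bool:
    s1 = (point - geom.plate1_centroid) @ geom.axis
    s2 = (point - geom.plate2_centroid) @ geom.axis
    return bool(s1 * s2 < 0)  # strictly inside the open slab


def classify_microtubule(
    trace: MTTrace,
    geom: SpindleGeometry,
    pole_radius: float = DEFAULT_POLE_RADIUS,
) -> str:
    """One of 'interpolar', 'mid_spindle', 'other' from the end points."""
    if pole_radius <= 0:
        raise ValueError("pole_radius must be > 0")
    e1, e2 = trace.ends
    near_pole = any(
        np.linalg.norm(e - c) <= pole_radius
        for e in (e1, e2)
        for c in (geom.centriole1, geom.centriole2)
    )
    if near_pole:
        return "interpolar"
    if _between_plates(e1, geom) and _between_plates(e2, geom):
        return "mid_spindle"
    return "other"


def summarize_population(
    traces: Iterable[MTTrace],
    geom: SpindleGeometry,
    pole_radius: float = DEFAULT_POLE_RADIUS,
) -> dict[str, int]:
    """Class counts plus total; counts always sum to the number of traces."""
    traces = list(traces)
    if not traces:
        raise ValueError("trace set is empty")
    counts = Counter(classify_microtubule(tr, geom, pole_radius) for tr in traces)
    out = {cls: int(counts.get(cls, 0)) for cls in CLASSES}
    out["total"] = len(traces)
    return out
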