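"""Morphometry of the tectorial membrane and organ of Corti.

Measurements are taken from annotator-supplied ROIs on section images: a closed
polygon over the tectorial membrane (TM), a closed polygon over the organ of
Corti (OoC), a polyline tracing the reticular lamina (the organ's apical
surface), and optionally an explicit width-measurement segment.  Outputs are

* ``gap``      — the shortest Euclidean distance between the TM boundary and
                 the surface polyline (0 when the structures touch/overlap);
* ``tm_area`` / ``ooc_area`` — pixel-count areas: number of pixels whose
                 centres fall inside the ROI times pixel_size^2;
* ``ooc_width`` — length of the width segment (or, as a fallback, the ROI's
                 extent along the basilar-membrane direction).

Coordinates are 0-based pixel indices (x = column, y = row); distances are
computed in continuous coordinates and scaled by ``pixel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon

__all__ = [
    "SectionGeometry",
    "SectionMeasurement",
    "roi_area",
    "min_gap",
    "ooc_width",
    "measure_section",
    "per_cochlea_average",
    "detachment_flag",
]


@dataclass
class SectionGeometry:
    tm_roi: np.ndarray  # (n, 2) closed polygon vertices, pixel coords (x, y)
    ooc_roi: np.ndarray
    reticular_lamina: np.ndarray  # (m, 2) open polyline
    basilar_membrane: np.ndarray | None = None
    width_line: np.ndarray | None = None  # (2, 2) segment
    pixel_size: float = 1.0  # um / pixel

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        self.tm_roi = _as_polygon_array(self.tm_roi, "tm_roi")
        self.ooc_roi = _as_polygon_array(self.ooc_roi, "ooc_roi")
        self.reticular_lamina = np.asarray(self.reticular_lamina, dtype=float)


@dataclass
class SectionMeasurement:
    gap: float  # um
    tm_area: float  # um^2
    ooc_area: float  # um^2
    ooc_width: float  # um
    location_index: int = 0
    cochlea_id: str | None = None
    n_averaged: int = 1

    def __post_init__(self) -> None:
        for name in ("gap", "tm_area", "ooc_area", "ooc_width"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{name} must be >= 0")


def _as_polygon_array(vertices: Sequence, name: str) -> np.ndarray:
    arr = np.asarray(vertices, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError(f"{name} must be an (n>=3, 2) vertex array")
    return arr


def _simple_polygon(vertices: np.ndarray, name: str = "polygon") -> Polygon:
    poly = Polygon(vertices)
    if not poly.is_valid or poly.area == 0:
        raise ValueError(f"{name} must be a simple (non-self-intersecting) polygon")
    return poly


def roi_area(roi: Sequence, pixel_size: float) -> float:
    """Pixel-count area: pixels whose centres fall inside the ROI, in um^2.

    Matches the measurement convention of counting included pixels rather than
    integrating the subpixel polygon (the shoelace area is the test oracle for
    the high-resolution limit).
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    arr = _as_polygon_array(roi, "roi")
    poly = _simple_polygon(arr, "roi")
    x0, y0, x1, y1 = poly.bounds
    xs = np.arange(int(np.floor(x0)), int(np.ceil(x1)) + 1)
    ys = np.arange(int(np.floor(y0)), int(np.ceil(y1)) + 1)
    xx, yy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(poly, xx.ravel().astype(float), yy.ravel().astype(float))
    return float(inside.sum()) * pixel_size**2


def min_gap(tm_roi: Sequence, surface: Sequence, pixel_size: float) -> float:
    """Shortest Euclidean distance (um) between the TM boundary and the surface.

    The distance is between the TM polygon's boundary *edges* and the surface
    polyline's edges (not just vertices); intersecting or overlapping
    geometries return 0 rather than a penetration depth.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    tm = _simple_polygon(_as_polygon_array(tm_roi, "tm_roi"), "tm_roi")
    surf = np.asarray(surface, dtype=float)
    if surf.ndim != 2 or surf.shape[1] != 2 or surf.shape[0] < 2:
        raise ValueError("surface must be an (n>=2, 2) polyline; single points are degenerate")
    line = LineString(surf)
    if line.length == 0:
        raise ValueError("degenerate surface polyline")
    if tm.intersects(line):
        return 0.0
    return float(tm.boundary.distance(line)) * pixel_size


def ooc_width(
    width_line: Sequence | None,
    pixel_size: float,
    ooc_roi: Sequence | None = None,
    basilar_direction: float = 0.0,
) -> float:
    """Organ-of-Corti width in um.

    Preferred input is the explicit measurement segment drawn across the organ.
    When only the ROI is available, the fallback is the ROI's extent along the
    basilar-membrane direction (``basilar_direction`` radians, default
    horizontal).
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if width_line is not None:
        seg = np.asarray(width_line, dtype=float)
        if seg.shape != (2, 2):
            raise ValueError("width_line must be a (2, 2) segment")
        return float(np.linalg.norm(seg[1] - seg[0])) * pixel_size
    if ooc_roi is None:
        raise ValueError("either width_line or ooc_roi must be provided")
    arr = _as_polygon_array(ooc_roi, "ooc_roi")
    _simple_polygon(arr, "ooc_roi")
    u = np.array([np.cos(basilar_direction), np.sin(basilar_direction)])
    proj = arr @ u
    return float(proj.max() - proj.min()) * pixel_size


def measure_section(
    geometry: SectionGeometry,
    location_index: int = 0,
    cochlea_id: str | None = None,
) -> SectionMeasurement:
    """All four measurements from one annotated section."""
    return SectionMeasurement(
        gap=min_gap(geometry.tm_roi, geometry.reticular_lamina, geometry.pixel_size),
        tm_area=roi_area(geometry.tm_roi, geometry.pixel_size),
        ooc_area=roi_area(geometry.ooc_roi, geometry.pixel_size),
        ooc_width=ooc_width(geometry.width_line, geometry.pixel_size, ooc_roi=geometry.ooc_roi),
        location_index=location_index,
        cochlea_id=cochlea_id,
    )


def per_cochlea_average(measurements: Sequence[SectionMeasurement]) -> SectionMeasurement:
    """Arithmetic mean of the per-location measurements of one cochlea."""
    if len(measurements) == 0:
        raise ValueError("no measurements to average")
    ids = {m.cochlea_id for m in measurements}
    if len(ids) != 1:
        raise ValueError(f"mixed cochlea ids: {sorted(map(str, ids))}")
    return SectionMeasurement(
        gap=float(np.mean([m.gap for m in measurements])),
        tm_area=float(np.mean([m.tm_area for m in measurements])),
        ooc_area=float(np.mean([m.ooc_area for m in measurements])),
        ooc_width=float(np.mean([m.ooc_width for m in measurements])),
        location_index=-1,
        cochlea_id=measurements[0].cochlea_id,
        n_averaged=len(measurements),
    )


def detachment_flag(measurement: SectionMeasurement, threshold: float = 0.0) -> bool:
    """True iff the TM-to-surface gap exceeds ``threshold`` um.

    The default threshold of 0 flags any measurable gap, matching the
    convention that control ears have no measurable gap.
    """
    return bool(measurement.gap > threshold)
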