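"""Nuclear morphometry.

Two complementary volume estimates for a (pro)nucleus:

* ``measure_diameter`` — threshold a central-section image, take the largest
  component, convert its area to an equivalent diameter, and derive sphere
  surface area (4*pi*r^2) and volume (4/3*pi*r^3).
* ``contour_volume`` — integrate traced per-slice contours: shoelace polygon
  area per slice times the slice spacing (0.1625 um by default, matching
  isotropic light-sheet sampling), summed over slices.

The theoretical volume from the widest slice and the integrated volume are
compared by ``sphericity_check``; nuclei are accepted as spherical when the
two agree within 10%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from shapely.geometry import Polygon as _ShapelyPolygon
from skimage import filters, measure

from .errors import GeometryError, InputError, SegmentationError
from .io import PointList


@dataclass
class NucleusGeometry:
    """Sphere geometry derived from an equivalent diameter."""

    diameter_um: float
    radius_um: float
    surface_area_um2: float
    volume_um3: float
    frame: int = 0
    time_s: float = 0.0

    @classmethod
    def from_diameter(cls, diameter_um: float, frame: int = 0,
                      time_s: float = 0.0) -> "NucleusGeometry":
        r = diameter_um / 2.0
        return cls(
            diameter_um=diameter_um,
            radius_um=r,
            surface_area_um2=4.0 * math.pi * r ** 2,
            volume_um3=(4.0 / 3.0) * math.pi * r ** 3,
            frame=frame,
            time_s=time_s,
        )


@dataclass
class ContourStack:
    """Closed per-slice polygons (vertices in um) at fixed slice spacing."""

    slices: list[tuple[int, np.ndarray]]  # (z_index, (N, 2) vertices)
    z_step_um: float = 0.1625
    object_id: str = "object"

    def __post_init__(self) -> None:
        if len(self.slices) < 1:
            raise GeometryError("contour stack needs at least one slice")
        if not (self.z_step_um > 0):
            raise InputError("z_step_um must be > 0")
        z = [int(s[0]) for s in self.slices]
        if not all(b > a for a, b in zip(z, z[1:])):
            raise GeometryError("slice indices must be strictly increasing")
        self.slices = [(int(zi), np.asarray(v, dtype=float))
                       for zi, v in self.slices]

    @classmethod
    def from_pointlists(cls, objects: Sequence[PointList],
                        z_step_um: float = 0.1625) -> "ContourStack":
        """Assemble the slices of one traced object (units um required)."""
        if not objects:
            raise GeometryError("no point lists given")
        ids = {o.object_id for o in objects}
        if len(ids) > 1:
            raise InputError(f"multiple object ids in one stack: {sorted(ids)}")
        units = {o.units for o in objects}
        if units != {"um"}:
            raise InputError(f"contour stacks require um units, got {units}")
        slices = sorted((o.slice_index, o.vertices) for o in objects)
        return cls(slices=list(slices), z_step_um=z_step_um,
                   object_id=objects[0].object_id)


@dataclass
class VolumeResult:
    integrated_um3: float
    theoretical_um3: float
    deviation: float          # |V_int - V_theo| / V_theo
    within_10pct: bool
    object_id: str = "object"


@dataclass
class GrowthRate:
    rate_um3_per_s: float
    intercept_um3: float
    r_squared: float
    stderr: float


def measure_diameter(frame: np.ndarray, pixel_size_um: float,
                     method: str = "otsu", min_area_px: int = 1,
                     frame_index: int = 0, time_s: float = 0.0,
                     ) -> NucleusGeometry:
    """Equivalent diameter of the largest thresholded component.

    diameter = 2 * sqrt(area / pi), converted to um; sphere surface area and
    volume follow exactly from it.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise InputError("frame must be 2-D")
    if np.ptp(frame) == 0:
        raise SegmentationError("constant frame cannot be thresholded")
    try:
        thresh_fn = getattr(filters, f"threshold_{method}")
    except AttributeError:
        raise InputError(f"unknown threshold method {method!r}") from None
    thr = float(thresh_fn(frame))
    mask = frame > thr
    labels = measure.label(mask)
    if labels.max() == 0:
        raise SegmentationError(f"empty mask at threshold {thr}")
    counts = np.bincount(labels.ravel())[1:]
    area_px = int(counts.max())
    if area_px < min_area_px:
        raise SegmentationError(
            f"largest component ({area_px} px) below min_area_px at "
            f"threshold {thr}"
        )
    diameter = 2.0 * math.sqrt(area_px / math.pi) * pixel_size_um
    return NucleusGeometry.from_diameter(diameter, frame=frame_index,
                                         time_s=time_s)


def polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of a simple closed polygon (orientation-independent)."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise GeometryError("vertices must be an (N, 2) array")
    if len(v) < 3:
        raise GeometryError("polygon needs >= 3 vertices")
    if not _ShapelyPolygon(v).is_valid:
        raise GeometryError("self-intersecting or degenerate polygon")
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def contour_volume(stack: ContourStack) -> float:
    """Sum of per-slice polygon areas times the slice spacing (um^3)."""
    total = 0.0
    for z, verts in stack.slices:
        try:
            total += polygon_area(verts)
        except GeometryError as exc:
            raise GeometryError(f"slice {z}: {exc}") from exc
    return total * stack.z_step_um


def theoretical_volume(stack: ContourStack) -> float:
    """Sphere volume from the widest (largest-area) slice.

    r = sqrt(max slice area / pi); V = 4/3 * pi * r^3.
    """
    areas = []
    for z, verts in stack.slices:
        try:
            areas.append(polygon_area(verts))
        except GeometryError as exc:
            raise GeometryError(f"slice {z}: {exc}") from exc
    r = math.sqrt(max(areas) / math.pi)
    return (4.0 / 3.0) * math.pi * r ** 3


def sphericity_check(stack: ContourStack) -> VolumeResult:
    """Compare integrated and theoretical volumes; flag within-10% agreement."""
    v_int = contour_volume(stack)
    v_theo = theoretical_volume(stack)
    if v_theo <= 0 or v_int <= 0:
        raise GeometryError("volumes must be positive")
    dev = abs(v_int - v_theo) / v_theo
    return VolumeResult(v_int, v_theo, dev, dev <= 0.10, stack.object_id)


def growth_rate(series: Sequence[tuple[float, float]]) -> GrowthRate:
    """OLS slope of volume vs time; the nuclear expansion rate in um^3/s."""
    pts = np.asarray(list(series), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise InputError("need >= 3 (time, volume) points")
    t, v = pts[:, 0], pts[:, 1]
    if len(np.unique(t)) != len(t):
        raise InputError("times must be distinct")
    res = stats.linregress(t, v)
    return GrowthRate(
        rate_um3_per_s=float(res.slope),
        intercept_um3=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        stderr=float(res.stderr),
    )
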