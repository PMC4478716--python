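"""Myocardial geometry: masks, transmural depth, AHA segments, local frames.

Conventions
-----------
Positions are in millimetres at pixel centres: ``x = col * spacing`` points
rightward, ``y = row * spacing`` downward, indices are 0-based. Angles are
measured from the +x axis, increasing with ``atan2(dy, dx)`` (the package's
"counterclockwise" convention; because y points down this appears clockwise
on screen, which only affects where segments are drawn, never the strain
algebra).

The left ventricle is divided into 16 AHA segments: six 60-degree sectors on
the basal and mid rings, four 90-degree sectors on the apical ring, apical
cap excluded. "Subendocardial" is the inner 50% of the wall measured from the
endocardial surface; "transmural" is the whole wall; "epicardial" is the
outer half.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import shapely
from shapely.geometry import LinearRing, Polygon

__all__ = [
    "ContourSet",
    "LayerMap",
    "SegmentModel",
    "LocalFrameField",
    "BASAL_NAMES",
    "APICAL_NAMES",
    "AHA_SEGMENTS",
    "VIEW_WALLS",
    "rasterize",
    "transmural_depth",
    "transmural_depth_at",
    "assign_segments",
    "assign_segments_la",
    "local_frames",
    "local_frames_la",
]

SA_KIND = "short-axis"
LA_KIND = "long-axis"

BASAL_NAMES = ("anterior", "anteroseptal", "inferoseptal",
               "inferior", "inferolateral", "anterolateral")
APICAL_NAMES = ("anterior", "septal", "inferior", "lateral")

#: segment id -> (ring, name), ids 1-16 per the AHA 16-segment model.
AHA_SEGMENTS: dict[int, tuple[str, str]] = {}
for _i, _n in enumerate(BASAL_NAMES):
    AHA_SEGMENTS[_i + 1] = ("basal", _n)
    AHA_SEGMENTS[_i + 7] = ("mid", _n)
for _i, _n in enumerate(APICAL_NAMES):
    AHA_SEGMENTS[_i + 13] = ("apical", _n)

_RING_BASE_ID = {"basal": 1, "mid": 7, "apical": 13}

#: Long-axis view -> wall-side -> basal/mid wall name represented by that wall.
VIEW_WALLS: dict[str, dict[str, str]] = {
    "two_chamber": {"right": "anterior", "left": "inferior"},
    "four_chamber": {"right": "anterolateral", "left": "inferoseptal"},
    "three_chamber": {"right": "inferolateral", "left": "anteroseptal"},
}

#: basal/mid wall name -> apical segment name (4-segment apical ring).
APICAL_MERGE = {
    "anterior": "anterior",
    "inferior": "inferior",
    "anteroseptal": "septal",
    "inferoseptal": "septal",
    "anterolateral": "lateral",
    "inferolateral": "lateral",
}

#: anatomical azimuth (deg) of each basal/mid wall centre under the default
#: reference angle (anterior centred at +90, counterclockwise ordering).
WALL_AZIMUTH_DEG = {
    "anterior": 90.0,
    "anteroseptal": 150.0,
    "inferoseptal": 210.0,
    "inferior": 270.0,
    "inferolateral": 330.0,
    "anterolateral": 30.0,
}


@dataclass
class ContourSet:
    """Endocardial and epicardial polygons for one slice, in mm.

    ``level`` is basal/mid/apical for short-axis slices; ``view`` identifies
    long-axis slices (two_chamber/three_chamber/four_chamber).
    ``reference_angle_deg`` is the angular centre of segment 1 (anterior);
    default +90.
    """

    endo: np.ndarray
    epi: np.ndarray
    slice_kind: str = SA_KIND
    level: str = "mid"
    view: str | None = None
    reference_angle_deg: float = 90.0
    meta: Mapping = field(default_factory=dict)

    def __post_init__(self):
        self.endo = np.asarray(self.endo, dtype=float)
        self.epi = np.asarray(self.epi, dtype=float)
        for name, poly in (("endo", self.endo), ("epi", self.epi)):
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                raise ValueError(f"{name} contour must be an (N>=3, 2) polygon")
            if not Polygon(poly).is_valid:
                raise ValueError(f"{name} contour is not a simple polygon")
        self.meta = dict(self.meta)

    @property
    def endo_polygon(self) -> Polygon:
        return Polygon(self.endo)

    @property
    def epi_polygon(self) -> Polygon:
        return Polygon(self.epi)

    @property
    def centroid_mm(self) -> np.ndarray:
        c = self.endo_polygon.centroid
        return np.array([c.x, c.y])


@dataclass
class LayerMap:
    """Per-pixel transmural depth in [0, 1] and layer label.

    Depth is 0 on the endocardial border and 1 on the epicardial border;
    ``subendocardial`` is True where depth < 0.5 (a tie at exactly 0.5 counts
    as epicardial, keeping the subendocardial layer strictly the inner half).
    """

    depth: np.ndarray
    subendocardial: np.ndarray
    mask: np.ndarray

    def layer_mask(self, layer: str) -> np.ndarray:
        if layer == "transmural":
            return self.mask
        if layer == "subendocardial":
            return self.mask & self.subendocardial
        if layer == "epicardial":
            return self.mask & ~self.subendocardial
        raise ValueError(f"unknown layer {layer!r}")


@dataclass
class SegmentModel:
    """Per-pixel AHA segment id (1-16; 0 outside the myocardium)."""

    segment_id: np.ndarray
    id_to_name: dict[int, str]
    kind: str = SA_KIND

    @property
    def ids(self) -> list[int]:
        present = np.unique(self.segment_id)
        return [int(i) for i in present if i > 0]


@dataclass
class LocalFrameField:
    """Orthonormal per-pixel direction fields.

    Short-axis slices carry ``radial`` (centroid to pixel) and
    ``circumferential`` (radial rotated by +90 degrees); long-axis slices
    carry ``longitudinal`` (base to apex) and ``radial`` (endo to epi across
    the wall). Arrays have shape (H, W, 2); NaN where undefined.
    """

    mask: np.ndarray
    radial: np.ndarray | None = None
    circumferential: np.ndarray | None = None
    longitudinal: np.ndarray | None = None

    def direction(self, name: str) -> np.ndarray:
        vec = {"radial_sa": self.radial, "radial_la": self.radial,
               "circumferential": self.circumferential,
               "longitudinal": self.longitudinal}.get(name)
        if vec is None:
            raise ValueError(f"direction {name!r} not available on this slice")
        return vec


def _pixel_coords(grid_shape, pixel_spacing_mm):
    rows, cols = np.mgrid[0:grid_shape[0], 0:grid_shape[1]]
    return cols * pixel_spacing_mm, rows * pixel_spacing_mm


def rasterize(contours: ContourSet, grid_shape: tuple[int, int],
              pixel_spacing_mm: float) -> np.ndarray:
    """Myocardial mask: pixel centres inside the epi and outside the endo polygon."""
    endo_poly = contours.endo_polygon
    epi_poly = contours.epi_polygon
    if not shapely.contains_properly(epi_poly, endo_poly):
        raise ValueError("endocardial contour must lie strictly inside the epicardial contour")
    x, y = _pixel_coords(grid_shape, pixel_spacing_mm)
    inside_epi = shapely.contains_xy(epi_poly, x.ravel(), y.ravel()).reshape(grid_shape)
    inside_endo = shapely.contains_xy(endo_poly, x.ravel(), y.ravel()).reshape(grid_shape)
    mask = inside_epi & ~inside_endo
    if not mask.any():
        raise ValueError("rasterized myocardial mask is empty")
    return mask


def transmural_depth(contours: ContourSet, mask: np.ndarray,
                     pixel_spacing_mm: float) -> LayerMap:
    """Transmural depth by dual distance to the endo and epi borders.

    depth = d_endo / (d_endo + d_epi), which is 0 on the endocardial border,
    1 on the epicardial border, and works for arbitrary simple contours.
    """
    mask = np.asarray(mask, dtype=bool)
    x, y = _pixel_coords(mask.shape, pixel_spacing_mm)
    pts = shapely.points(np.column_stack([x[mask], y[mask]]))
    endo_ring = LinearRing(contours.endo)
    epi_ring = LinearRing(contours.epi)
    d_endo = shapely.distance(pts, endo_ring)
    d_epi = shapely.distance(pts, epi_ring)
    total = d_endo + d_epi
    total[total == 0] = np.finfo(float).eps
    depth_vals = d_endo / total
    depth = np.full(mask.shape, np.nan)
    depth[mask] = depth_vals
    subendo = np.zeros(mask.shape, dtype=bool)
    subendo[mask] = depth_vals < 0.5
    return LayerMap(depth, subendo, mask)


def transmural_depth_at(contours: ContourSet, point_mm) -> tuple[float, str]:
    """Depth and layer label at a single point; errors outside the wall."""
    pt = shapely.points(np.asarray(point_mm, dtype=float))
    inside = contours.epi_polygon.covers(pt) and not contours.endo_polygon.contains(pt)
    if not inside:
        raise ValueError("point lies outside the myocardial wall")
    d_endo = float(shapely.distance(pt, LinearRing(contours.endo)))
    d_epi = float(shapely.distance(pt, LinearRing(contours.epi)))
    depth = d_endo / max(d_endo + d_epi, np.finfo(float).eps)
    return depth, ("subendocardial" if depth < 0.5 else "epicardial")


def _sector_index(theta_deg: np.ndarray, reference_angle_deg: float, n_sectors: int) -> np.ndarray:
    width = 360.0 / n_sectors
    start = reference_angle_deg - width / 2.0
    return np.floor(np.mod(theta_deg - start, 360.0) / width).astype(int)


def assign_segments(mask: np.ndarray, level: str, reference_angle_deg: float = 90.0,
                    centroid_mm=None, pixel_spacing_mm: float = 1.0) -> SegmentModel:
    """AHA segment labels for a short-axis ring.

    Angular sectors proceed counterclockwise (package convention) from
    segment 1, whose centre sits at ``reference_angle_deg``. Basal and mid
    rings have six 60-degree sectors; the apical ring has four 90-degree
    sectors.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if level not in _RING_BASE_ID:
        raise ValueError(f"unknown slice level {level!r}")
    names = APICAL_NAMES if level == "apical" else BASAL_NAMES
    x, y = _pixel_coords(mask.shape, pixel_spacing_mm)
    if centroid_mm is None:
        centroid_mm = np.array([x[mask].mean(), y[mask].mean()])
    theta = np.degrees(np.arctan2(y - centroid_mm[1], x - centroid_mm[0]))
    idx = _sector_index(theta, reference_angle_deg, len(names))
    base = _RING_BASE_ID[level]
    seg = np.where(mask, base + idx, 0).astype(np.int16)
    id_to_name = {base + i: n for i, n in enumerate(names)}
    return SegmentModel(seg, id_to_name, kind=SA_KIND)


def assign_segments_la(mask: np.ndarray, view: str, center_x_mm: float | None = None,
                       pixel_spacing_mm: float = 1.0) -> SegmentModel:
    """AHA segment labels for a long-axis slice.

    The long axis runs along y (base at larger y, apex at smaller y); the
    slice is split into level thirds along it. Each wall side represents the
    anatomical wall its view cuts through (see ``VIEW_WALLS``); on the apical
    ring, wall names merge into the four apical segments.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if view not in VIEW_WALLS:
        raise ValueError(f"unknown long-axis view {view!r}")
    x, y = _pixel_coords(mask.shape, pixel_spacing_mm)
    if center_x_mm is None:
        center_x_mm = x[mask].mean()
    ys = y[mask]
    ymin, ymax = ys.min(), ys.max()
    span = max(ymax - ymin, np.finfo(float).eps)
    # apex (small y) -> apical; base (large y) -> basal
    frac = (y - ymin) / span
    level_idx = np.clip(np.floor(frac * 3.0).astype(int), 0, 2)  # 0 apical, 1 mid, 2 basal
    side_right = x >= center_x_mm

    seg = np.zeros(mask.shape, dtype=np.int16)
    id_to_name: dict[int, str] = {}
    for right in (True, False):
        wall = VIEW_WALLS[view]["right" if right else "left"]
        for li, ring in ((2, "basal"), (1, "mid"), (0, "apical")):
            name = APICAL_MERGE[wall] if ring == "apical" else wall
            ring_names = APICAL_NAMES if ring == "apical" else BASAL_NAMES
            sid = _RING_BASE_ID[ring] + ring_names.index(name)
            sel = mask & (level_idx == li) & (side_right == right)
            seg[sel] = sid
            if sel.any():
                id_to_name[sid] = name
    return SegmentModel(seg, id_to_name, kind=LA_KIND)


def local_frames(mask: np.ndarray, centroid_mm, pixel_spacing_mm: float = 1.0,
                 min_radius_mm: float = 1e-6) -> LocalFrameField:
    """Short-axis radial/circumferential unit-vector fields.

    Radial points from the cavity centroid to the pixel; circumferential is
    radial rotated by +90 degrees ((1,0) -> (0,1)). Pixels closer to the
    centroid than ``min_radius_mm`` are undefined and excluded.
    """
    mask = np.asarray(mask, dtype=bool)
    x, y = _pixel_coords(mask.shape, pixel_spacing_mm)
    dx = x - centroid_mm[0]
    dy = y - centroid_mm[1]
    r = np.hypot(dx, dy)
    ok = mask & (r > min_radius_mm)
    with np.errstate(invalid="ignore", divide="ignore"):
        rx = np.where(ok, dx / r, np.nan)
        ry = np.where(ok, dy / r, np.nan)
    radial = np.stack([rx, ry], axis=-1)
    circ = np.stack([-ry, rx], axis=-1)
    return LocalFrameField(mask=ok, radial=radial, circumferential=circ)


def local_frames_la(mask: np.ndarray, center_x_mm: float,
                    pixel_spacing_mm: float = 1.0) -> LocalFrameField:
    """Long-axis longitudinal/radial unit-vector fields.

    Longitudinal is (0, -1): from base (larger y) toward apex under the
    image convention. Radial points across the wall from endo to epi,
    i.e. away from the cavity centreline.
    """
    mask = np.asarray(mask, dtype=bool)
    x, _ = _pixel_coords(mask.shape, pixel_spacing_mm)
    sx = np.where(x >= center_x_mm, 1.0, -1.0)
    radial = np.stack([np.where(mask, sx, np.nan),
                       np.where(mask, 0.0, np.nan)], axis=-1)
    longit = np.stack([np.where(mask, 0.0, np.nan),
                       np.where(mask, -1.0, np.nan)], axis=-1)
    return LocalFrameField(mask=mask, radial=radial, longitudinal=longit)
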