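"""Analytic left-ventricular phantoms with known deformation and scar.

Short-axis slices are circular annuli deformed by the area-preserving
contraction ``r(R) = sqrt(R^2 - (R_endo^2 - r_endo^2))`` composed with a
rigid twist; long-axis slices are rectangular wall frames deformed by the
incompressible stretch ``x' = x / lambda_L``, ``y' = lambda_L * y`` about the
slice centre. Both maps have closed-form deformation gradients, so every
downstream stage (encoding, unwrapping, decoding, strain, statistics) can be
checked against exact ground truth.

Scar sectors reduce the displacement amplitude multiplicatively: inside a
sector the displacement is ``s * u`` with ``s = contraction_scale``, blended
to 1 with a cosine ramp of angular half-width ``transition_deg`` outside the
sector. Where the scale is locally constant the deformation gradient is
``F = I + s (F_full - I)``, which is the closed form used by
:func:`analytic_strain`; inside the blending zone no closed form exists and
the strain oracle refuses (or returns NaN on request).

The cohort generator emulates the study conditions: control, mixed
(pathological but scar-free, globally hypokinetic) and scar groups, three SA
plus three LA slices per subject, balanced three-point encoding at
ke = 0.30 cycles/pixel and complex Gaussian noise at the requested SNR.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import anatomy
from .anatomy import SA_KIND, LA_KIND, ContourSet, WALL_AZIMUTH_DEG, VIEW_WALLS
from .dense_sim import ComplexImageSet, EncodingScheme, encode
from .recon import DisplacementField

__all__ = [
    "PhantomGeometry",
    "DeformationParams",
    "ScarSector",
    "WallMotionMode",
    "CohortSpec",
    "Subject",
    "PhantomSlice",
    "SA_LEVEL_RADII",
    "analytic_displacement",
    "analytic_deformation_gradient",
    "analytic_strain",
    "scar_scale",
    "circle_polygon",
    "generate_subject",
    "generate_cohort",
]

#: default (endo, epi) radii in mm per short-axis level.
SA_LEVEL_RADII = {"basal": (25.0, 35.0), "mid": (23.0, 33.0), "apical": (20.0, 30.0)}

LA_VIEWS = ("two_chamber", "four_chamber", "three_chamber")


@dataclass(frozen=True)
class PhantomGeometry:
    """Reference (end-diastolic) geometry of one phantom slice.

    Short-axis slices use ``endo_radius_mm``/``epi_radius_mm``; long-axis
    slices are rectangular frames described by ``cavity_halfwidth_mm``,
    ``wall_thickness_mm`` and ``wall_length_mm``. The default pixel spacing
    is the reconstructed DENSE resolution of 1.36 mm on a 96x96 grid.
    """

    slice_kind: str = SA_KIND
    endo_radius_mm: float = 25.0
    epi_radius_mm: float = 35.0
    wall_thickness_mm: float = 10.0
    wall_length_mm: float = 80.0
    cavity_halfwidth_mm: float = 20.0
    grid_shape: tuple[int, int] = (96, 96)
    pixel_spacing_mm: float = 1.36
    center_mm: tuple[float, float] | None = None
    level: str = "mid"
    view: str | None = None

    def __post_init__(self):
        if self.slice_kind not in (SA_KIND, LA_KIND):
            raise ValueError(f"unknown slice_kind {self.slice_kind!r}")
        if not self.pixel_spacing_mm > 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if self.slice_kind == SA_KIND:
            if not (self.epi_radius_mm > self.endo_radius_mm > 0):
                raise ValueError("require epi_radius_mm > endo_radius_mm > 0")
        else:
            if self.view is not None and self.view not in VIEW_WALLS:
                raise ValueError(f"unknown long-axis view {self.view!r}")
            if not (self.wall_thickness_mm > 0 and self.wall_length_mm > 0
                    and self.cavity_halfwidth_mm > 0):
                raise ValueError("long-axis dimensions must be positive")
        cx, cy = self.center
        ext_x = (self.grid_shape[1] - 1) * self.pixel_spacing_mm
        ext_y = (self.grid_shape[0] - 1) * self.pixel_spacing_mm
        if self.slice_kind == SA_KIND:
            rx = ry = self.epi_radius_mm
        else:
            rx = self.cavity_halfwidth_mm + self.wall_thickness_mm
            ry = self.wall_length_mm / 2.0
        if cx - rx < 0 or cx + rx > ext_x or cy - ry < 0 or cy + ry > ext_y:
            raise ValueError("phantom does not fit inside the grid")

    @property
    def center(self) -> np.ndarray:
        if self.center_mm is not None:
            return np.asarray(self.center_mm, dtype=float)
        return np.array([(self.grid_shape[1] - 1) / 2.0,
                         (self.grid_shape[0] - 1) / 2.0]) * self.pixel_spacing_mm

    def pixel_centers(self) -> np.ndarray:
        """(H, W, 2) array of pixel-centre positions in mm."""
        rows, cols = np.mgrid[0:self.grid_shape[0], 0:self.grid_shape[1]]
        return np.stack([cols * self.pixel_spacing_mm,
                         rows * self.pixel_spacing_mm], axis=-1)

    def contours(self, n_points: int = 256,
                 reference_angle_deg: float = 90.0) -> ContourSet:
        """Reference contours (polygons in mm) for this slice."""
        cx, cy = self.center
        if self.slice_kind == SA_KIND:
            endo = circle_polygon((cx, cy), self.endo_radius_mm, n_points)
            epi = circle_polygon((cx, cy), self.epi_radius_mm, n_points)
        else:
            whw = self.cavity_halfwidth_mm + self.wall_thickness_mm
            hl = self.wall_length_mm / 2.0
            epi = np.array([[cx - whw, cy - hl], [cx + whw, cy - hl],
                            [cx + whw, cy + hl], [cx - whw, cy + hl]])
            ihl = hl - self.wall_thickness_mm
            c = self.cavity_halfwidth_mm
            endo = np.array([[cx - c, cy - ihl], [cx + c, cy - ihl],
                             [cx + c, cy + ihl], [cx - c, cy + ihl]])
        return ContourSet(endo, epi, slice_kind=self.slice_kind, level=self.level,
                          view=self.view, reference_angle_deg=reference_angle_deg)


def circle_polygon(center, radius: float, n_points: int = 256) -> np.ndarray:
    th = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    return np.column_stack([center[0] + radius * np.cos(th),
                            center[1] + radius * np.sin(th)])


@dataclass(frozen=True)
class ScarSector:
    """Angular/transmural scar region with reduced contraction.

    ``contraction_scale`` multiplies the local displacement amplitude
    (1 = normal tissue, 0 = fully akinetic). The angular window blends to
    normal tissue with a cosine ramp of width ``transition_deg`` beyond each
    edge; the transmural window [depth_start, depth_end] may optionally blend
    over ``depth_transition`` (fraction of wall thickness).
    """

    angle_start_deg: float
    angle_end_deg: float
    contraction_scale: float
    depth_start: float = 0.0
    depth_end: float = 1.0
    transition_deg: float = 10.0
    depth_transition: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.contraction_scale <= 1.0:
            raise ValueError("contraction_scale must be in [0, 1]")
        if not self.depth_start < self.depth_end:
            raise ValueError("require depth_start < depth_end")
        if self.transition_deg < 0 or self.depth_transition < 0:
            raise ValueError("transition widths must be non-negative")

    @property
    def center_deg(self) -> float:
        span = np.mod(self.angle_end_deg - self.angle_start_deg, 360.0)
        return float(np.mod(self.angle_start_deg + span / 2.0, 360.0))

    @property
    def halfwidth_deg(self) -> float:
        return float(np.mod(self.angle_end_deg - self.angle_start_deg, 360.0) / 2.0)

    def weight(self, theta_deg, depth):
        """Blending weight in [0, 1]: 1 in the scar core, 0 in normal tissue."""
        theta_deg = np.asarray(theta_deg, dtype=float)
        depth = np.asarray(depth, dtype=float)
        delta = np.abs(np.mod(theta_deg - self.center_deg + 180.0, 360.0) - 180.0)
        hw, tr = self.halfwidth_deg, self.transition_deg
        if tr > 0:
            ramp = np.clip((delta - hw) / tr, 0.0, 1.0)
            w_ang = 0.5 * (1.0 + np.cos(np.pi * ramp))
            w_ang = np.where(delta <= hw, 1.0, np.where(delta >= hw + tr, 0.0, w_ang))
        else:
            w_ang = (delta <= hw).astype(float)
        dt = self.depth_transition
        if dt > 0:
            lo = np.clip((depth - (self.depth_start - dt)) / dt, 0.0, 1.0)
            hi = np.clip(((self.depth_end + dt) - depth) / dt, 0.0, 1.0)
            w_dep = np.minimum(lo, hi)
            inside = (depth >= self.depth_start) & (depth <= self.depth_end)
            w_dep = np.where(inside, 1.0, w_dep)
        else:
            w_dep = ((depth >= self.depth_start) & (depth <= self.depth_end)).astype(float)
        return w_ang * w_dep

    def core(self, theta_deg, depth):
        """Boolean core region (full scar weight, no blending)."""
        theta_deg = np.asarray(theta_deg, dtype=float)
        depth = np.asarray(depth, dtype=float)
        delta = np.abs(np.mod(theta_deg - self.center_deg + 180.0, 360.0) - 180.0)
        return (delta <= self.halfwidth_deg) & (depth >= self.depth_start) & (depth <= self.depth_end)


@dataclass(frozen=True)
class WallMotionMode:
    """Wall-thickening heterogeneity: a radial perturbation linear in depth.

    The deformed radius gains ``amplitude_mm * depth * cos(order * theta +
    phase)``: the endocardial surface is untouched, the epicardial surface is
    displaced, so radial (thickening) strain is perturbed uniformly across
    the wall while circumferential shortening barely changes. This emulates
    the through-plane effects that make in-plane slices deviate from 2D
    incompressibility in vivo, and it is the dominant source of the larger
    radial strain variability seen in controls. The perturbed map still has a
    closed-form deformation gradient.
    """

    amplitude_mm: float
    angular_order: int = 0
    angular_phase_deg: float = 0.0

    def __post_init__(self):
        if self.angular_order < 0:
            raise ValueError("angular_order must be non-negative")


@dataclass(frozen=True)
class DeformationParams:
    """Analytic deformation of one slice.

    ``endo_radius_deformed_mm`` sets the short-axis contraction (None keeps
    the reference radius, i.e. no contraction); ``twist_deg`` adds a rigid
    rotation; ``longitudinal_stretch`` is the long-axis stretch ratio
    lambda_L in (0, 1] (the across-wall stretch is 1/lambda_L by 2D
    incompressibility). ``wall_motion_modes`` add wall-thickening
    heterogeneity on top (zero by default, keeping the exactly
    area-preserving family).
    """

    endo_radius_deformed_mm: float | None = None
    twist_deg: float = 0.0
    longitudinal_stretch: float = 1.0
    scar_sectors: tuple[ScarSector, ...] = ()
    wall_motion_modes: tuple[WallMotionMode, ...] = ()

    def __post_init__(self):
        if self.endo_radius_deformed_mm is not None and not self.endo_radius_deformed_mm > 0:
            raise ValueError("endo_radius_deformed_mm must be positive")
        if not 0.0 < self.longitudinal_stretch <= 1.0:
            raise ValueError("longitudinal_stretch must be in (0, 1]")
        object.__setattr__(self, "scar_sectors", tuple(self.scar_sectors))
        object.__setattr__(self, "wall_motion_modes", tuple(self.wall_motion_modes))


def _theta_depth(geom: PhantomGeometry, pts: np.ndarray):
    """Anatomical azimuth (deg) and transmural depth used for scar weighting."""
    d = pts - geom.center
    if geom.slice_kind == SA_KIND:
        R = np.hypot(d[..., 0], d[..., 1])
        theta = np.degrees(np.arctan2(d[..., 1], d[..., 0]))
        depth = np.clip((R - geom.endo_radius_mm)
                        / (geom.epi_radius_mm - geom.endo_radius_mm), 0.0, 1.0)
        return theta, depth
    # Long-axis: each wall stands for an anatomical wall of its view; use
    # that wall's azimuth so scar placement is consistent with the SA slices.
    if geom.view is not None:
        right_az = WALL_AZIMUTH_DEG[VIEW_WALLS[geom.view]["right"]]
        left_az = WALL_AZIMUTH_DEG[VIEW_WALLS[geom.view]["left"]]
    else:
        right_az, left_az = 0.0, 180.0
    theta = np.where(d[..., 0] >= 0, right_az, left_az)
    depth = np.clip((np.abs(d[..., 0]) - geom.cavity_halfwidth_mm)
                    / geom.wall_thickness_mm, 0.0, 1.0)
    return theta, depth


def scar_scale(geom: PhantomGeometry, deform: DeformationParams, pts: np.ndarray):
    """Displacement scale s in [0, 1] and a transition-zone flag per point.

    s = 1 - max_i (1 - contraction_scale_i) * w_i over scar sectors; the
    transition flag marks points where any sector weight is strictly between
    0 and 1 (no closed-form strain there).
    """
    pts = np.asarray(pts, dtype=float)
    theta, depth = _theta_depth(geom, pts)
    reduction = np.zeros(pts.shape[:-1])
    transition = np.zeros(pts.shape[:-1], dtype=bool)
    for sec in deform.scar_sectors:
        w = sec.weight(theta, depth)
        if sec.contraction_scale < 1.0:
            transition |= (w > 0.0) & (w < 1.0)
        reduction = np.maximum(reduction, (1.0 - sec.contraction_scale) * w)
    return 1.0 - reduction, transition


def _inside_footprint(geom: PhantomGeometry, pts: np.ndarray, tol_mm: float):
    d = pts - geom.center
    if geom.slice_kind == SA_KIND:
        R = np.hypot(d[..., 0], d[..., 1])
        return (R >= geom.endo_radius_mm - tol_mm) & (R <= geom.epi_radius_mm + tol_mm)
    whw = geom.cavity_halfwidth_mm + geom.wall_thickness_mm
    hl = geom.wall_length_mm / 2.0
    ihl = hl - geom.wall_thickness_mm
    ax, ay = np.abs(d[..., 0]), np.abs(d[..., 1])
    inside_epi = (ax <= whw + tol_mm) & (ay <= hl + tol_mm)
    inside_endo = (ax < geom.cavity_halfwidth_mm - tol_mm) & (ay < ihl - tol_mm)
    return inside_epi & ~inside_endo


def _mode_terms(deform: DeformationParams, theta: np.ndarray, depth: np.ndarray):
    """Radial perturbation delta_r and its depth/angle derivatives.

    delta_r = sum_j a_j * depth * cos(m_j * theta + psi_j); returns
    (delta_r, d(delta_r)/d(depth), d(delta_r)/d(theta)).
    """
    dr = np.zeros_like(depth)
    ddr_ddepth = np.zeros_like(depth)
    ddr_dtheta = np.zeros_like(depth)
    for mode in deform.wall_motion_modes:
        ang = mode.angular_order * theta + np.radians(mode.angular_phase_deg)
        c = np.cos(ang)
        dr += mode.amplitude_mm * depth * c
        ddr_ddepth += mode.amplitude_mm * c
        ddr_dtheta += -mode.amplitude_mm * depth * mode.angular_order * np.sin(ang)
    return dr, ddr_ddepth, ddr_dtheta


def _full_map(geom: PhantomGeometry, deform: DeformationParams, pts: np.ndarray):
    """Deformed positions under the unscarred analytic map."""
    d = pts - geom.center
    if geom.slice_kind == SA_KIND:
        R = np.hypot(d[..., 0], d[..., 1])
        theta = np.arctan2(d[..., 1], d[..., 0])
        r_endo = (geom.endo_radius_mm if deform.endo_radius_deformed_mm is None
                  else deform.endo_radius_deformed_mm)
        c = geom.endo_radius_mm ** 2 - r_endo ** 2
        r = np.sqrt(np.maximum(R ** 2 - c, 0.0))
        if deform.wall_motion_modes:
            depth = np.clip((R - geom.endo_radius_mm)
                            / (geom.epi_radius_mm - geom.endo_radius_mm), 0.0, 1.0)
            dr, _, _ = _mode_terms(deform, theta, depth)
            r = r + dr
        phi = theta + np.radians(deform.twist_deg)
        return geom.center + np.stack([r * np.cos(phi), r * np.sin(phi)], axis=-1)
    lam = deform.longitudinal_stretch
    x = d[..., 0] / lam
    if deform.wall_motion_modes:
        theta_w, depth = _theta_depth(geom, pts)
        dr, _, _ = _mode_terms(deform, np.radians(theta_w), depth)
        x = x + np.sign(d[..., 0]) * dr
    return geom.center + np.stack([x, d[..., 1] * lam], axis=-1)


def analytic_displacement(geom: PhantomGeometry, deform: DeformationParams,
                          points_mm, tol_mm: float = 1e-9) -> np.ndarray:
    """Closed-form displacement (mm) at reference positions.

    Points outside the myocardial footprint (beyond ``tol_mm``) are flagged
    missing (NaN), never extrapolated.
    """
    pts = np.asarray(points_mm, dtype=float)
    inside = _inside_footprint(geom, pts, tol_mm)
    u_full = _full_map(geom, deform, pts) - pts
    s, _ = scar_scale(geom, deform, pts)
    u = s[..., None] * u_full
    u = np.where(inside[..., None], u, np.nan)
    return u


def _full_gradient(geom: PhantomGeometry, deform: DeformationParams, pts: np.ndarray):
    """Deformation gradient of the unscarred map, shape (..., 2, 2).

    In polar bases the short-axis map (R, theta) -> (r(R, theta), theta + a)
    has the triangular gradient
    ``F = r_R e_r' (x) e_R + (r_theta / R) e_r' (x) e_T + (r / R) e_t' (x) e_T``
    with the primed basis at the rotated angle; without wall-motion modes the
    shear term vanishes and F reduces to diag(dr/dR, r/R) rotated by the twist.
    """
    d = pts - geom.center
    if geom.slice_kind == SA_KIND:
        R = np.hypot(d[..., 0], d[..., 1])
        theta = np.arctan2(d[..., 1], d[..., 0])
        r_endo = (geom.endo_radius_mm if deform.endo_radius_deformed_mm is None
                  else deform.endo_radius_deformed_mm)
        c = geom.endo_radius_mm ** 2 - r_endo ** 2
        r0 = np.sqrt(np.maximum(R ** 2 - c, np.finfo(float).tiny))
        r_R = R / r0        # d r0 / dR
        r = r0
        r_theta = np.zeros_like(R)
        if deform.wall_motion_modes:
            wall = geom.epi_radius_mm - geom.endo_radius_mm
            depth = np.clip((R - geom.endo_radius_mm) / wall, 0.0, 1.0)
            dr, ddr_dd, ddr_dth = _mode_terms(deform, theta, depth)
            r = r0 + dr
            r_R = r_R + ddr_dd / wall
            r_theta = ddr_dth
        ct, st = np.cos(theta), np.sin(theta)
        eR = np.stack([ct, st], axis=-1)
        eT = np.stack([-st, ct], axis=-1)
        a = np.radians(deform.twist_deg)
        phi = theta + a
        erp = np.stack([np.cos(phi), np.sin(phi)], axis=-1)
        etp = np.stack([-np.sin(phi), np.cos(phi)], axis=-1)
        F = (r_R[..., None, None] * erp[..., :, None] * eR[..., None, :]
             + (r_theta / R)[..., None, None] * erp[..., :, None] * eT[..., None, :]
             + (r / R)[..., None, None] * etp[..., :, None] * eT[..., None, :])
        return F
    lam = deform.longitudinal_stretch
    F = np.zeros(pts.shape[:-1] + (2, 2))
    F[..., 0, 0] = 1.0 / lam
    F[..., 1, 1] = lam
    if deform.wall_motion_modes:
        theta_w, depth = _theta_depth(geom, pts)
        _, ddr_dd, _ = _mode_terms(deform, np.radians(theta_w), depth)
        in_wall = (depth > 0.0) & (depth < 1.0)
        F[..., 0, 0] = F[..., 0, 0] + np.where(
            in_wall, ddr_dd / geom.wall_thickness_mm, 0.0)
    return F


def analytic_deformation_gradient(geom: PhantomGeometry, deform: DeformationParams,
                                  points_mm, tol_mm: float = 1e-9,
                                  on_transition: str = "raise") -> np.ndarray:
    """Closed-form deformation gradient F at reference positions.

    Valid only where the scar scale is locally constant; inside a blending
    zone the closed form does not hold and the function raises (default) or
    returns NaN (``on_transition="nan"``).
    """
    pts = np.asarray(points_mm, dtype=float)
    inside = _inside_footprint(geom, pts, tol_mm)
    s, transition = scar_scale(geom, deform, pts)
    if on_transition == "raise":
        if np.any(transition & inside):
            raise ValueError("point(s) inside a scar transition zone: no closed-form strain")
    elif on_transition != "nan":
        raise ValueError("on_transition must be 'raise' or 'nan'")
    F_full = _full_gradient(geom, deform, pts)
    eye = np.eye(2)
    F = eye + s[..., None, None] * (F_full - eye)
    bad = ~inside | transition
    F = np.where(bad[..., None, None], np.nan, F)
    return F


def analytic_strain(geom: PhantomGeometry, deform: DeformationParams, points_mm,
                    tol_mm: float = 1e-9, on_transition: str = "raise") -> dict:
    """Closed-form Green-Lagrange strain (percent) by direction.

    Short-axis points yield ``radial_sa`` and ``circumferential``; long-axis
    points yield ``radial_la`` and ``longitudinal``. Directions are evaluated
    in the reference configuration (Lagrangian convention), so a rigid twist
    contributes zero strain.
    """
    pts = np.asarray(points_mm, dtype=float)
    F = analytic_deformation_gradient(geom, deform, pts, tol_mm, on_transition)
    E = 0.5 * (np.einsum("...ji,...jk->...ik", F, F) - np.eye(2))
    d = pts - geom.center
    if geom.slice_kind == SA_KIND:
        R = np.hypot(d[..., 0], d[..., 1])
        R = np.where(R > 0, R, np.nan)
        er = np.stack([d[..., 0] / R, d[..., 1] / R], axis=-1)
        et = np.stack([-er[..., 1], er[..., 0]], axis=-1)
        return {
            "radial_sa": 100.0 * np.einsum("...i,...ij,...j->...", er, E, er),
            "circumferential": 100.0 * np.einsum("...i,...ij,...j->...", et, E, et),
        }
    return {
        "radial_la": 100.0 * E[..., 0, 0],
        "longitudinal": 100.0 * E[..., 1, 1],
    }


# ----------------------------------------------------------------------------
# subject and cohort generation
# ----------------------------------------------------------------------------

@dataclass
class PhantomSlice:
    """One generated slice: geometry, deformation, contours, images, truth."""

    geom: PhantomGeometry | None
    deform: DeformationParams | None
    contours: ContourSet
    mask: np.ndarray
    images: ComplexImageSet
    truth_displacement: DisplacementField | None = None
    truth_strain: dict | None = None
    scar_core: np.ndarray | None = None


@dataclass
class Subject:
    """A generated phantom subject: 3 SA + 3 LA slices plus ground truth."""

    subject_id: str
    group: str
    slices: list
    scar_fractions: np.ndarray  # (16,), index = segment id - 1
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters for the synthetic cohort.

    Defaults encode the conditions the pipeline is validated under: 20
    control and 20 scar subjects at SNR 20, one transmural scar sector per
    scar subject with contraction_scale 0.4 and angular width 80-110 degrees
    (wide enough that at least one 60-degree segment is covered over more
    than 60% of its area, i.e. above the >50% detection endpoint), and
    modest physiological between-subject variability in contraction, twist
    and longitudinal shortening.
    """

    n_control: int = 20
    n_mixed: int = 0
    n_scar: int = 20
    snr: float = 20.0
    seed: int = 0
    noise_seed: int | None = None
    contraction_scale_range: tuple[float, float] = (0.4, 0.4)
    sector_width_deg_range: tuple[float, float] = (80.0, 110.0)
    sector_depth: tuple[float, float] = (0.0, 1.0)
    transition_deg: float = 10.0
    n_sectors: int = 1
    contraction_ratio_mean: float = 0.80
    contraction_ratio_sd: float = 0.015
    twist_mean_deg: float = 4.0
    twist_sd_deg: float = 1.0
    longitudinal_stretch_mean: float = 0.87
    longitudinal_stretch_sd: float = 0.02
    mixed_scale_range: tuple[float, float] = (0.75, 0.95)
    wall_motion_amp_sd_mm: float = 0.4
    wall_motion_orders: tuple[int, ...] = (0, 1, 2)
    center_jitter_px: float = 0.5
    grid_shape: tuple[int, int] = (96, 96)
    pixel_spacing_mm: float = 1.36
    reference_angle_deg: float = 90.0

    def __post_init__(self):
        if min(self.n_control, self.n_mixed, self.n_scar) < 0:
            raise ValueError("group counts must be non-negative")
        if not self.snr > 0:
            raise ValueError("snr must be positive")


def _subject_geometries(grid_shape, pixel_spacing_mm, center_offset_mm):
    gs = tuple(grid_shape)
    px = float(pixel_spacing_mm)
    base_center = np.array([(gs[1] - 1) / 2.0, (gs[0] - 1) / 2.0]) * px
    center = tuple(base_center + center_offset_mm)
    sa = {level: PhantomGeometry(SA_KIND, endo_radius_mm=r0, epi_radius_mm=r1,
                                 grid_shape=gs, pixel_spacing_mm=px,
                                 center_mm=center, level=level)
          for level, (r0, r1) in SA_LEVEL_RADII.items()}
    la = {view: PhantomGeometry(LA_KIND, grid_shape=gs, pixel_spacing_mm=px,
                                center_mm=center, level="mixed", view=view)
          for view in LA_VIEWS}
    return sa, la


def generate_subject(subject_id: str, group: str, params: dict, *,
                     snr: float = 20.0, seed=None,
                     grid_shape=(96, 96), pixel_spacing_mm=1.36,
                     reference_angle_deg: float = 90.0,
                     scheme: EncodingScheme | None = None) -> Subject:
    """Generate one subject: 3 SA + 3 LA encoded slices with ground truth.

    ``params`` holds the subject-level deformation: ``contraction_ratio``
    (deformed/reference endocardial radius), ``twist_deg``,
    ``longitudinal_stretch`` and ``scar_sectors``. Deterministic given
    ``seed`` (anything acceptable to :class:`numpy.random.SeedSequence`).
    """
    scheme = scheme or EncodingScheme()
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    slice_seeds = ss.spawn(6)

    offset = np.asarray(params.get("center_offset_mm", (0.0, 0.0)), dtype=float)
    sa_geoms, la_geoms = _subject_geometries(grid_shape, pixel_spacing_mm, offset)

    rho = float(params.get("contraction_ratio", 0.8))
    twist = float(params.get("twist_deg", 4.0))
    lam = float(params.get("longitudinal_stretch", 0.87))
    sectors = tuple(params.get("scar_sectors", ()))
    modes = tuple(params.get("wall_motion_modes", ()))

    slices = []
    scar_counts = np.zeros(16)
    seg_counts = np.zeros(16)
    k = 0
    for level in ("basal", "mid", "apical"):
        geom = sa_geoms[level]
        deform = DeformationParams(endo_radius_deformed_mm=rho * geom.endo_radius_mm,
                                   twist_deg=twist, scar_sectors=sectors,
                                   wall_motion_modes=modes)
        sl = _generate_slice(geom, deform, scheme, snr, slice_seeds[k],
                             subject_id, reference_angle_deg)
        slices.append(sl)
        # ground-truth scar fraction per AHA segment, from SA slices
        segs = anatomy.assign_segments(sl.mask, level, reference_angle_deg,
                                       centroid_mm=geom.center,
                                       pixel_spacing_mm=geom.pixel_spacing_mm)
        for sid in segs.ids:
            in_seg = segs.segment_id == sid
            seg_counts[sid - 1] += in_seg.sum()
            if sl.scar_core is not None:
                scar_counts[sid - 1] += (in_seg & sl.scar_core).sum()
        k += 1
    for view in LA_VIEWS:
        geom = la_geoms[view]
        deform = DeformationParams(longitudinal_stretch=lam, scar_sectors=sectors,
                                   wall_motion_modes=modes)
        sl = _generate_slice(geom, deform, scheme, snr, slice_seeds[k],
                             subject_id, reference_angle_deg)
        slices.append(sl)
        k += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = np.where(seg_counts > 0, scar_counts / seg_counts, 0.0)
    return Subject(subject_id, group, slices, fractions, dict(params))


def _generate_slice(geom, deform, scheme, snr, seed_seq, subject_id,
                    reference_angle_deg):
    contours = geom.contours(reference_angle_deg=reference_angle_deg)
    mask = anatomy.rasterize(contours, geom.grid_shape, geom.pixel_spacing_mm)
    pts = geom.pixel_centers()
    # pixel centres inside the polygonized contours sit inside the analytic
    # footprint to within the polygonization error; allow a small tolerance
    u_map = analytic_displacement(geom, deform, pts, tol_mm=0.05)
    u = np.stack([np.where(mask, u_map[..., 0], np.nan),
                  np.where(mask, u_map[..., 1], np.nan)])
    truth = DisplacementField(u, mask, geom.pixel_spacing_mm, provenance="ground-truth")
    strain_maps = analytic_strain(geom, deform, pts, tol_mm=0.05, on_transition="nan")
    strain_maps = {k: np.where(mask, v, np.nan) for k, v in strain_maps.items()}
    meta = {"subject_id": subject_id, "slice_kind": geom.slice_kind,
            "level": geom.level, "view": geom.view,
            "frame_label": "aortic_valve_closure",
            "reference_angle_deg": reference_angle_deg}
    rng = np.random.default_rng(seed_seq)
    images = encode(truth, scheme, snr=snr, rng=rng, meta=meta)
    theta, depth = _theta_depth(geom, pts)
    core = np.zeros(mask.shape, dtype=bool)
    for sec in deform.scar_sectors:
        if sec.contraction_scale < 1.0:
            core |= sec.core(theta, depth)
    core &= mask
    return PhantomSlice(geom, deform, contours, mask, images, truth,
                        strain_maps, core if deform.scar_sectors else None)


def _sample_params(rng: np.random.Generator, spec: CohortSpec, group: str) -> dict:
    rho = float(np.clip(rng.normal(spec.contraction_ratio_mean, spec.contraction_ratio_sd),
                        0.70, 0.92))
    twist = float(rng.normal(spec.twist_mean_deg, spec.twist_sd_deg))
    lam = float(np.clip(rng.normal(spec.longitudinal_stretch_mean,
                                   spec.longitudinal_stretch_sd), 0.80, 0.97))
    jit = spec.center_jitter_px * spec.pixel_spacing_mm
    offset = rng.uniform(-jit, jit, size=2)
    modes = tuple(
        WallMotionMode(amplitude_mm=float(rng.normal(0.0, spec.wall_motion_amp_sd_mm)),
                       angular_order=int(order),
                       angular_phase_deg=float(rng.uniform(0.0, 360.0)))
        for order in spec.wall_motion_orders) if spec.wall_motion_amp_sd_mm > 0 else ()
    sectors = ()
    if group == "mixed":
        gs = float(rng.uniform(*spec.mixed_scale_range))
        # globally hypokinetic but scar-free: shrink the whole deformation
        rho = 1.0 - gs * (1.0 - rho)
        twist = gs * twist
        lam = 1.0 - gs * (1.0 - lam)
    elif group == "scar":
        secs = []
        for _ in range(spec.n_sectors):
            width = float(rng.uniform(*spec.sector_width_deg_range))
            center = float(rng.uniform(0.0, 360.0))
            cs = float(rng.uniform(*spec.contraction_scale_range))
            secs.append(ScarSector(angle_start_deg=center - width / 2.0,
                                   angle_end_deg=center + width / 2.0,
                                   contraction_scale=cs,
                                   depth_start=spec.sector_depth[0],
                                   depth_end=spec.sector_depth[1],
                                   transition_deg=spec.transition_deg))
        sectors = tuple(secs)
    return {"contraction_ratio": rho, "twist_deg": twist,
            "longitudinal_stretch": lam, "center_offset_mm": tuple(offset),
            "scar_sectors": sectors, "wall_motion_modes": modes}


def generate_cohort(spec: CohortSpec) -> list[Subject]:
    """Generate the control / mixed / scar cohort, reproducible per seed.

    Subject-level parameters derive from ``spec.seed``; the acquisition noise
    derives from ``spec.noise_seed`` when given (else from the same root), so
    a scan-rescan experiment is two calls differing only in ``noise_seed``.
    """
    n_total = spec.n_control + spec.n_mixed + spec.n_scar
    if n_total == 0:
        raise ValueError("cohort is empty: all group counts are zero")
    root = np.random.SeedSequence(spec.seed)
    params_children = root.spawn(n_total)
    noise_root = (np.random.SeedSequence(spec.noise_seed)
                  if spec.noise_seed is not None else root.spawn(1)[0])
    noise_children = noise_root.spawn(n_total)

    groups = (["control"] * spec.n_control + ["mixed"] * spec.n_mixed
              + ["scar"] * spec.n_scar)
    counters = {"control": 0, "mixed": 0, "scar": 0}
    subjects = []
    for i, group in enumerate(groups):
        counters[group] += 1
        sid = f"{group[:4]}{counters[group]:02d}"
        rng = np.random.default_rng(params_children[i])
        params = _sample_params(rng, spec, group)
        subj = generate_subject(sid, group, params, snr=spec.snr,
                                seed=noise_children[i],
                                grid_shape=spec.grid_shape,
                                pixel_spacing_mm=spec.pixel_spacing_mm,
                                reference_angle_deg=spec.reference_angle_deg)
        subjects.append(subj)
    return subjects
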