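"""Inverse DENSE path: wrapped multipoint phases to in-plane displacement.

The reconstruction proceeds in three steps:

1. ``phase_differences`` — pairwise differences of the balanced multipoint
   phases. The shared background phase cancels exactly; each difference map
   carries an effective encoding vector ``e_i - e_j``.
2. ``unwrap`` — quality-guided region growing restores the continuous phase
   of each difference map up to a global multiple of 2*pi.
3. ``decode`` — per-pixel least squares inverts ``2*pi*ke*(E_eff u) = phi``
   and converts pixels to millimetres.

Displacement is expressed on the reference (encoded) grid, so strain computed
from it downstream is Lagrangian by construction.
"""
from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .dense_sim import ComplexImageSet, EncodingScheme, wrap_phase

__all__ = [
    "DisplacementField",
    "QualityMap",
    "UnwrapResult",
    "phase_differences",
    "quality_map",
    "unwrap",
    "decode",
    "reconstruct_displacement",
]


@dataclass
class DisplacementField:
    """In-plane displacement on the reference grid.

    Attributes
    ----------
    u : ndarray, shape (2, H, W)
        Displacement in mm; index 0 is the x (column) component, index 1 the
        y (row) component. Undefined (NaN) outside the mask.
    mask : ndarray of bool
    pixel_spacing_mm : float
    provenance : str
        "decoded" or "ground-truth".
    """

    u: np.ndarray
    mask: np.ndarray
    pixel_spacing_mm: float
    provenance: str = "decoded"

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.u.shape != (2,) + self.mask.shape:
            raise ValueError("u must have shape (2, H, W) matching mask")
        if not self.pixel_spacing_mm > 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if not np.all(np.isfinite(self.u[:, self.mask])):
            raise ValueError("displacement must be finite inside the mask")

    @property
    def u_px(self) -> np.ndarray:
        """Displacement in pixels."""
        return self.u / self.pixel_spacing_mm


@dataclass
class QualityMap:
    """Per-pixel unwrapping reliability; higher is more reliable."""

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("quality and mask shapes differ")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("quality must be finite inside the mask")


@dataclass
class UnwrapResult:
    """Unwrapped phase plus bookkeeping about connected components."""

    values: np.ndarray
    n_components: int
    seeds: list
    component_map: np.ndarray


def phase_differences(images: ComplexImageSet):
    """Pairwise wrapped phase differences of a balanced multipoint set.

    Uses the pairs (0,1) and (1,2); any constant or smooth background phase
    common to all directions cancels identically.

    Returns
    -------
    diffs : ndarray, shape (2, H, W)
        Wrapped difference maps.
    eff_vectors : ndarray, shape (2, 2)
        Effective encoding vectors ``e_i - e_j`` for each difference map.
    """
    if images.scheme.n_directions < 3:
        raise ValueError("balanced decoding requires at least 3 encoding directions")
    if not images.scheme.balanced:
        raise ValueError("encoding scheme is not balanced (directions do not sum to zero)")
    dirs = images.scheme.direction_matrix
    pairs = ((0, 1), (1, 2))
    diffs = np.stack([wrap_phase(images.phases[i] - images.phases[j]) for i, j in pairs])
    eff = np.stack([dirs[i] - dirs[j] for i, j in pairs])
    return diffs, eff


def quality_map(wrapped: np.ndarray, mask: np.ndarray, eps: float = 1e-6) -> QualityMap:
    """Unwrapping quality from local wrapped-phase-gradient variance.

    Quality is the inverse of the summed 3x3-window variances of the wrapped
    horizontal and vertical phase gradients; smooth regions score high,
    residue-prone regions low. Deterministic, no randomness involved.
    """
    wrapped = np.asarray(wrapped, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    grads = []
    gx = np.zeros_like(wrapped)
    valid_x = mask[:, 1:] & mask[:, :-1]
    gx[:, :-1] = np.where(valid_x, wrap_phase(np.where(valid_x, wrapped[:, 1:] - wrapped[:, :-1], 0.0)), 0.0)
    grads.append(gx)
    gy = np.zeros_like(wrapped)
    valid_y = mask[1:, :] & mask[:-1, :]
    gy[:-1, :] = np.where(valid_y, wrap_phase(np.where(valid_y, wrapped[1:, :] - wrapped[:-1, :], 0.0)), 0.0)
    grads.append(gy)

    var = np.zeros_like(wrapped)
    for g in grads:
        m1 = uniform_filter(g, size=3, mode="constant")
        m2 = uniform_filter(g * g, size=3, mode="constant")
        var += np.maximum(m2 - m1 * m1, 0.0)
    values = 1.0 / (eps + var)
    values[~mask] = 0.0
    return QualityMap(values, mask)


def unwrap(wrapped: np.ndarray, mask: np.ndarray, quality=None,
           seed_pixel: tuple[int, int] | None = None) -> UnwrapResult:
    """Quality-guided region-growing phase unwrapping.

    Starting from the seed (the highest-quality pixel by default), pixels are
    absorbed in order of decreasing quality; each new pixel receives the
    value of its already-unwrapped neighbour plus the wrapped difference, so
    neighbour jumps along the growth path are at most pi in magnitude. A true
    jump of exactly pi is resolved as +pi (the wrap convention keeps the
    boundary). The seed pixel keeps its wrapped value, fixing the global
    2*pi*k of its component.

    Disconnected mask components are unwrapped independently, each anchored
    at its own best-quality seed, and flagged via ``n_components`` and
    ``component_map``.
    """
    wrapped = np.asarray(wrapped, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if wrapped.shape != mask.shape:
        raise ValueError("wrapped and mask shapes differ")
    if not mask.any():
        raise ValueError("empty mask")
    if quality is None:
        q = quality_map(wrapped, mask).values
    elif isinstance(quality, QualityMap):
        q = quality.values
    else:
        q = np.asarray(quality, dtype=float)

    H, W = mask.shape
    out = wrapped.copy()
    visited = ~mask
    comp = np.zeros(mask.shape, dtype=np.int32)
    seeds: list[tuple[int, int]] = []
    two_pi = 2.0 * np.pi

    def best_unvisited():
        flat = np.where(~visited, q, -np.inf)
        idx = int(np.argmax(flat))
        if not np.isfinite(flat.flat[idx]):
            return None
        return divmod(idx, W)

    n_components = 0
    first = True
    while True:
        if first and seed_pixel is not None:
            sr, sc = seed_pixel
            if not mask[sr, sc]:
                raise ValueError("seed_pixel must lie inside the mask")
            seed = (sr, sc)
        else:
            seed = best_unvisited()
            if seed is None:
                break
        first = False
        n_components += 1
        seeds.append(seed)
        sr, sc = seed
        visited[sr, sc] = True
        comp[sr, sc] = n_components
        heap = [(-q[sr, sc], sr * W + sc)]
        while heap:
            _, flat_idx = heapq.heappop(heap)
            r, c = divmod(flat_idx, W)
            base = out[r, c]
            for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if 0 <= nr < H and 0 <= nc < W and not visited[nr, nc]:
                    d = wrapped[nr, nc] - base
                    d -= two_pi * np.floor((d + np.pi) / two_pi)
                    if d <= -np.pi:  # keep (-pi, pi] convention
                        d += two_pi
                    out[nr, nc] = base + d
                    visited[nr, nc] = True
                    comp[nr, nc] = n_components
                    heapq.heappush(heap, (-q[nr, nc], nr * W + nc))
    out[~mask] = np.nan
    return UnwrapResult(out, n_components, seeds, comp)


def decode(diffs: np.ndarray, eff_vectors: np.ndarray, scheme: EncodingScheme,
           pixel_spacing_mm: float, mask: np.ndarray) -> DisplacementField:
    """Least-squares inversion of unwrapped phase differences to displacement.

    Solves ``2*pi*ke * (E_eff u_px) = phi`` per pixel, where ``E_eff`` stacks
    the effective encoding vectors, then converts pixels to mm.
    """
    diffs = np.asarray(diffs, dtype=float)
    eff = np.asarray(eff_vectors, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if diffs.ndim != 3 or diffs.shape[0] != eff.shape[0]:
        raise ValueError("diffs must be (m, H, W) matching eff_vectors (m, 2)")
    A = 2.0 * np.pi * scheme.ke_cycles_per_pixel * eff
    if np.linalg.matrix_rank(A, tol=1e-9) < 2:
        raise ValueError("effective encoding vectors are rank deficient")
    pinv = np.linalg.pinv(A)  # (2, m)
    phi = np.where(mask, diffs, 0.0).reshape(diffs.shape[0], -1)
    u_px = (pinv @ phi).reshape(2, *mask.shape)
    u_mm = u_px * float(pixel_spacing_mm)
    u_mm[:, ~mask] = np.nan
    return DisplacementField(u_mm, mask, float(pixel_spacing_mm), provenance="decoded")


def reconstruct_displacement(images: ComplexImageSet, *, recenter: bool = True,
                             return_quality: bool = False):
    """Full inverse path: wrapped phases to a displacement field in mm.

    Pairwise differencing removes the background phase, each difference map
    is unwrapped by quality-guided region growing, and (optionally) the
    undetermined global 2*pi cycle of each map is fixed by shifting its
    mask-mean phase into ``(-pi, pi]`` — appropriate for myocardial motion,
    which is approximately zero-mean over the wall for contraction and twist
    about the cavity centre.
    """
    diffs, eff = phase_differences(images)
    mask = images.mask
    unwrapped = np.empty_like(diffs)
    qualities = []
    for k in range(diffs.shape[0]):
        qm = quality_map(diffs[k], mask)
        res = unwrap(diffs[k], mask, qm)
        vals = res.values
        if recenter:
            shift = 2.0 * np.pi * np.round(np.nanmean(vals[mask]) / (2.0 * np.pi))
            vals = vals - shift
        unwrapped[k] = np.where(mask, vals, 0.0)
        qualities.append(qm)
    fieldout = decode(unwrapped, eff, images.scheme, images.pixel_spacing_mm, mask)
    if return_quality:
        return fieldout, qualities
    return fieldout
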