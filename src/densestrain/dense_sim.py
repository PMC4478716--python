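"""Forward DENSE encoding: displacement fields to wrapped multipoint phase images.

In DENSE (Displacement Encoding with Stimulated Echoes) MRI, the in-plane
tissue displacement accumulated since the encoding pulse is stored in the
per-voxel signal phase: a displacement ``u`` (in pixels) along an in-plane
encoding direction ``e`` contributes ``2*pi*ke*(e . u)`` radians of phase,
where ``ke`` is the encoding strength in cycles per pixel. Balanced
multipoint encoding acquires three (or more) directions whose unit vectors
sum to zero, so that the shared background phase (coil and off-resonance
effects) cancels exactly in pairwise phase differences.

This module implements the forward model only: phase synthesis, phase
wrapping into ``(-pi, pi]`` and complex Gaussian receiver noise. The inverse
path (unwrapping and least-squares decoding back to displacement) lives in
:mod:`densestrain.recon`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = ["DEFAULT_DIRECTIONS", "EncodingScheme", "ComplexImageSet", "wrap_phase", "encode"]

_SQRT3_2 = float(np.sqrt(3.0) / 2.0)

#: Balanced three-point scheme at 0, 120 and 240 degrees.
DEFAULT_DIRECTIONS: tuple[tuple[float, float], ...] = (
    (1.0, 0.0),
    (-0.5, _SQRT3_2),
    (-0.5, -_SQRT3_2),
)


def wrap_phase(phase):
    """Wrap phase (radians) into the half-open interval ``(-pi, pi]``.

    The boundary convention keeps ``+pi`` and maps ``-pi`` to ``+pi``, so the
    output is the unique representative of ``phase`` modulo ``2*pi`` in
    ``(-pi, pi]``.

    Parameters
    ----------
    phase : array_like
        Phase in radians; must be finite.

    Returns
    -------
    float or ndarray
        Wrapped phase, scalar if the input was scalar.
    """
    arr = np.asarray(phase, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("wrap_phase requires finite input")
    wrapped = np.pi - np.mod(np.pi - arr, 2.0 * np.pi)
    if arr.ndim == 0:
        return float(wrapped)
    return wrapped


@dataclass(frozen=True)
class EncodingScheme:
    """Displacement-encoding scheme.

    Parameters
    ----------
    ke_cycles_per_pixel : float
        Encoding strength: phase cycles accumulated per pixel of
        displacement along the encoding direction. Default 0.30, i.e. one
        full phase cycle per ~3.33 px of displacement.
    directions : tuple of (float, float)
        In-plane unit encoding vectors. The default is the balanced
        three-point set at 0deg/120deg/240deg.
    """

    ke_cycles_per_pixel: float = 0.30
    directions: tuple[tuple[float, float], ...] = DEFAULT_DIRECTIONS

    def __post_init__(self):
        if not self.ke_cycles_per_pixel > 0:
            raise ValueError("ke_cycles_per_pixel must be positive")
        dirs = np.asarray(self.directions, dtype=float)
        if dirs.ndim != 2 or dirs.shape[1] != 2 or dirs.shape[0] < 1:
            raise ValueError("directions must be a non-empty sequence of 2-vectors")
        if not np.allclose(np.linalg.norm(dirs, axis=1), 1.0, atol=1e-9):
            raise ValueError("encoding directions must be unit vectors")

    @property
    def direction_matrix(self) -> np.ndarray:
        """Encoding directions as an (n, 2) array."""
        return np.asarray(self.directions, dtype=float)

    @property
    def n_directions(self) -> int:
        return len(self.directions)

    @property
    def balanced(self) -> bool:
        """True when the direction vectors sum to zero."""
        return bool(np.allclose(self.direction_matrix.sum(axis=0), 0.0, atol=1e-9))


@dataclass
class ComplexImageSet:
    """Per-direction wrapped phase images plus magnitude for one slice.

    Attributes
    ----------
    phases : ndarray, shape (n_dir, H, W)
        Wrapped phase in ``(-pi, pi]`` per encoding direction.
    magnitude : ndarray, shape (H, W)
        Signal magnitude (direction-averaged).
    mask : ndarray of bool, shape (H, W)
        Myocardium footprint on the reference grid.
    scheme : EncodingScheme
    pixel_spacing_mm : float
    meta : dict
        Slice metadata: ``slice_kind`` ("short-axis"/"long-axis"), ``level``
        or ``view``, ``frame_label``, ``subject_id`` and similar.
    """

    phases: np.ndarray
    magnitude: np.ndarray
    mask: np.ndarray
    scheme: EncodingScheme
    pixel_spacing_mm: float
    meta: Mapping = field(default_factory=dict)

    def __post_init__(self):
        self.phases = np.asarray(self.phases, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.phases.ndim != 3:
            raise ValueError("phases must have shape (n_dir, H, W)")
        if self.phases.shape[0] != self.scheme.n_directions:
            raise ValueError("phase map count does not match encoding directions")
        if self.phases.shape[1:] != self.mask.shape or self.magnitude.shape != self.mask.shape:
            raise ValueError("all maps must share one grid shape")
        if np.any(self.phases <= -np.pi - 1e-12) or np.any(self.phases > np.pi + 1e-12):
            raise ValueError("phases must lie in (-pi, pi]")
        if not self.pixel_spacing_mm > 0:
            raise ValueError("pixel_spacing_mm must be positive")
        self.meta = dict(self.meta)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.mask.shape


def encode(field, scheme: EncodingScheme | None = None, *, snr: float = np.inf,
           background_phase=0.0, seed: int | None = None,
           rng: np.random.Generator | None = None, meta: Mapping | None = None) -> ComplexImageSet:
    """Encode a displacement field into wrapped multipoint phase images.

    Per direction ``e`` the noiseless phase is
    ``wrap(2*pi*ke*(e . u_px) + background_phase)`` where ``u_px`` is the
    displacement in pixels. With finite ``snr``, complex Gaussian noise with
    per-channel standard deviation ``magnitude / snr`` is added to the
    complex signal before the phase is extracted, so the phase noise at high
    SNR is approximately ``1/snr`` radians inside the mask.

    Parameters
    ----------
    field : DisplacementField-like
        Object exposing ``u`` (2, H, W) in mm, ``mask`` and
        ``pixel_spacing_mm``.
    scheme : EncodingScheme, optional
        Defaults to the balanced three-point scheme at ke = 0.30.
    snr : float
        Magnitude signal-to-noise ratio; ``inf`` for noiseless.
    background_phase : float or ndarray
        Common phase offset (scalar or per-pixel map) shared by all
        directions, as produced by coil and off-resonance effects.
    seed, rng :
        Randomness for the noise; ``rng`` wins when both are given.
    meta : dict, optional
        Slice metadata copied onto the output.

    Returns
    -------
    ComplexImageSet
    """
    if scheme is None:
        scheme = EncodingScheme()
    mask = np.asarray(field.mask, dtype=bool)
    u = np.asarray(field.u, dtype=float)
    if u.shape != (2,) + mask.shape:
        raise ValueError("field.u must have shape (2, H, W)")
    u_px = np.where(mask, u, 0.0) / float(field.pixel_spacing_mm)
    bg = np.broadcast_to(np.asarray(background_phase, dtype=float), mask.shape)

    two_pi_ke = 2.0 * np.pi * scheme.ke_cycles_per_pixel
    true_phase = np.stack([
        two_pi_ke * (e[0] * u_px[0] + e[1] * u_px[1]) + bg
        for e in scheme.direction_matrix
    ])
    mag0 = mask.astype(float)

    if np.isinf(snr):
        phases = wrap_phase(true_phase)
        magnitude = mag0
    else:
        if not snr > 0:
            raise ValueError("snr must be positive or infinite")
        if rng is None:
            rng = np.random.default_rng(seed)
        sigma = mag0 / float(snr)
        signal = mag0 * np.exp(1j * true_phase)
        noise = sigma * (rng.standard_normal(true_phase.shape)
                         + 1j * rng.standard_normal(true_phase.shape))
        z = signal + noise
        phases = np.angle(z)  # (-pi, pi]
        magnitude = np.abs(z).mean(axis=0)

    return ComplexImageSet(phases, magnitude, mask, scheme,
                           float(field.pixel_spacing_mm), dict(meta or {}))
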