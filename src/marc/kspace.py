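"""Rigid-motion phase-error simulation in k-space.

Respiratory motion between phase-encode line acquisitions displaces the
object, which by the Fourier shift theorem multiplies each k-space line
k_y by a phase factor exp(i*phi(k_y)). For a sinusoidal (breathing-like)
displacement the phase error is

    phi(k_y) = 0                                     for |k_y| <  k_y0
    phi(k_y) = 2*pi * k_y * D * sin(a*t(k_y) + b)/N  for |k_y| >= k_y0

where D is the displacement amplitude in pixels, a the respiratory phase
advance per acquired line, b a random phase offset, N the number of
phase-encode lines and t(k_y) the acquisition-time index of line k_y
(t = k_y for linear ordering, centre-out rank for centric ordering).
The central band |k_y| < k_y0 is left untouched so image contrast is
preserved. Corruption is phase-only: the magnitude of every k-space
line is unchanged and image energy is conserved.

Signed-index convention: profiles are stored in centred order, entry i
corresponding to k_y = i - N//2, i.e. k_y in [-N/2, N/2) with DC at the
centre (an ``fftshift``-style layout).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from .core import AcquisitionGeometry, PhaseStack

__all__ = [
    "MotionParams",
    "PhaseErrorProfile",
    "signed_ky",
    "centric_time_index",
    "delta_px_from_cm",
    "alpha_from_freq",
    "phase_error_periodic",
    "phase_error_random",
    "phase_error_profile",
    "apply_phase_error",
    "corrupt_image",
    "corrupt_stack",
]

MotionMode = Literal["periodic", "random"]

# Physiological/protocol envelope used as simulation defaults:
# breathing at 0.2-0.7 Hz, displacement up to 2.6 cm, centre band +-20 px.
DELTA_CM_RANGE = (0.0, 2.6)
FREQ_HZ_RANGE = (0.2, 0.7)
DEFAULT_KY0_PX = 20


@dataclass(frozen=True)
class MotionParams:
    """Parameters of one simulated respiratory motion event.

    delta_cm
        Displacement amplitude (significance of motion), cm; 0-2.6 cm is
        the realistic respiratory range.
    freq_hz
        Respiratory frequency, Hz (0.2-0.7 Hz for free breathing). Only
        used in periodic mode.
    beta_rad
        Phase offset of the sine wave, radians in [-pi, pi].
    ky0_px
        Half-width of the protected central k-space band, px.
    mode
        "periodic" — coherent sinusoidal breathing; "random" — irregular
        line-by-line displacements.
    seed
        Seed for the random mode draws.
    """

    delta_cm: float
    freq_hz: float = 0.4
    beta_rad: float = 0.0
    ky0_px: int = DEFAULT_KY0_PX
    mode: MotionMode = "periodic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta_cm < 0:
            raise ValueError(f"delta_cm must be >= 0, got {self.delta_cm}")
        if self.ky0_px < 0:
            raise ValueError(f"ky0_px must be >= 0, got {self.ky0_px}")
        if self.mode not in ("periodic", "random"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "periodic" and self.freq_hz <= 0:
            raise ValueError("freq_hz must be > 0 in periodic mode")


@dataclass(frozen=True)
class PhaseErrorProfile:
    """Per-line phase error phi(k_y), radians, in centred k_y order."""

    phi: np.ndarray
    ky: np.ndarray
    ky0_px: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "phi", np.asarray(self.phi, dtype=float))
        object.__setattr__(self, "ky", np.asarray(self.ky, dtype=int))
        if self.phi.shape != self.ky.shape or self.phi.ndim != 1:
            raise ValueError("phi and ky must be 1-D arrays of equal length")
        if np.any(self.phi[np.abs(self.ky) < self.ky0_px] != 0.0):
            raise ValueError("phase error inside the protected centre band")

    def __len__(self) -> int:
        return len(self.phi)


def signed_ky(n: int) -> np.ndarray:
    """Centred signed k_y indices, [-n//2, n - n//2), DC at position n//2."""
    return np.arange(n) - n // 2


def centric_time_index(n: int) -> np.ndarray:
    """Acquisition-time rank of each centred k_y under centre-out ordering.

    DC is acquired first, then lines of increasing |k_y|, the positive line
    before the negative one at equal |k_y|. Returns a permutation of 0..n-1.
    """
    ky = signed_ky(n)
    order = np.lexsort((ky < 0, np.abs(ky)))
    t = np.empty(n, dtype=int)
    t[order] = np.arange(n)
    return t


def delta_px_from_cm(delta_cm: float, geometry: AcquisitionGeometry) -> float:
    """Convert physical displacement (cm) to phase-encode pixels."""
    return delta_cm * 10.0 / geometry.pixel_mm


def alpha_from_freq(freq_hz: float, geometry: AcquisitionGeometry) -> float:
    """Respiratory phase advance per acquired k-space line, radians."""
    n = geometry.n_phase_encodes
    return 2.0 * math.pi * freq_hz * geometry.readout_duration_s / n


def _check_band(n: int, ky0: int) -> None:
    if 2 * ky0 >= n:
        raise ValueError(
            f"protected band 2*ky0={2 * ky0} must be smaller than N={n}"
        )


def phase_error_profile(
    geometry: AcquisitionGeometry,
    delta_px: float,
    alpha: float,
    beta: float,
    ky0_px: int,
) -> PhaseErrorProfile:
    """Sinusoidal phase-error profile from pixel-unit parameters.

    phi(k_y) = 2*pi*k_y*delta_px*sin(alpha*t + b)/N outside the protected
    band, with t = k_y (linear ordering) or the centric acquisition rank.
    """
    n = geometry.n_phase_encodes
    _check_band(n, ky0_px)
    ky = signed_ky(n)
    if geometry.ordering == "linear":
        t = ky.astype(float)
    else:
        t = centric_time_index(n).astype(float)
    phi = 2.0 * np.pi * ky * delta_px * np.sin(alpha * t + beta) / n
    phi[np.abs(ky) < ky0_px] = 0.0
    return PhaseErrorProfile(phi=phi, ky=ky, ky0_px=ky0_px)


def phase_error_periodic(
    geometry: AcquisitionGeometry, params: MotionParams
) -> PhaseErrorProfile:
    """Phase-error profile for coherent sinusoidal respiration."""
    if params.mode != "periodic":
        raise ValueError(f"params.mode must be 'periodic', got {params.mode!r}")
    return phase_error_profile(
        geometry,
        delta_px=delta_px_from_cm(params.delta_cm, geometry),
        alpha=alpha_from_freq(params.freq_hz, geometry),
        beta=params.beta_rad,
        ky0_px=params.ky0_px,
    )


def phase_error_random(
    geometry: AcquisitionGeometry, params: MotionParams
) -> PhaseErrorProfile:
    """Phase-error profile for irregular respiration.

    Seeded two-stage draw: the number M of affected lines is uniform on
    {0, ..., N - 2*ky0}; M lines are then chosen without replacement
    outside the protected band, and each gets an independent displacement
    d ~ U[-delta_px, +delta_px], i.e. phi = 2*pi*k_y*d/N.
    """
    if params.mode != "random":
        raise ValueError(f"params.mode must be 'random', got {params.mode!r}")
    n = geometry.n_phase_encodes
    _check_band(n, params.ky0_px)
    ky = signed_ky(n)
    phi = np.zeros(n)
    delta_px = delta_px_from_cm(params.delta_cm, geometry)
    rng = np.random.default_rng(params.seed)
    eligible = np.flatnonzero(np.abs(ky) >= params.ky0_px)
    m_max = min(n - 2 * params.ky0_px, eligible.size)
    m = int(rng.integers(0, m_max + 1))
    if m > 0:
        lines = rng.choice(eligible, size=m, replace=False)
        d = rng.uniform(-delta_px, delta_px, size=m)
        phi[lines] = 2.0 * np.pi * ky[lines] * d / n
    return PhaseErrorProfile(phi=phi, ky=ky, ky0_px=params.ky0_px)


def make_profile(geometry: AcquisitionGeometry, params: MotionParams) -> PhaseErrorProfile:
    """Dispatch on ``params.mode``."""
    if params.mode == "periodic":
        return phase_error_periodic(geometry, params)
    return phase_error_random(geometry, params)


def apply_phase_error(
    kspace_centred: np.ndarray,
    profile: PhaseErrorProfile,
    geometry: AcquisitionGeometry,
) -> np.ndarray:
    """Multiply each phase-encode line of a centred k-space by exp(i*phi).

    Lines inside the protected band (phi = 0) are bit-identical after the
    call; no line's magnitude changes.
    """
    axis = geometry.phase_encode_dim
    if kspace_centred.shape[axis] != len(profile):
        raise ValueError(
            f"profile length {len(profile)} does not match k-space extent "
            f"{kspace_centred.shape[axis]} along the phase-encode axis"
        )
    shape = [1, 1]
    shape[axis] = len(profile)
    return kspace_centred * np.exp(1j * profile.phi).reshape(shape)


def corrupt_image(
    image: np.ndarray,
    profile: PhaseErrorProfile,
    geometry: AcquisitionGeometry,
) -> np.ndarray:
    """Corrupt a real 2-D magnitude image with a phase-error profile.

    Forward FFT, per-line phase multiplication, inverse FFT, magnitude.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"image must be 2-D, got ndim={image.ndim}")
    k = np.fft.fftshift(np.fft.fft2(image))
    k = apply_phase_error(k, profile, geometry)
    return np.abs(np.fft.ifft2(np.fft.ifftshift(k)))


def corrupt_stack(
    stack: PhaseStack,
    params_per_phase: Sequence[Optional[MotionParams]],
) -> PhaseStack:
    """Corrupt each phase of a stack independently.

    ``params_per_phase`` has one entry per phase; ``None`` leaves that
    phase bit-identical to the input (some phases of a multi-arterial
    acquisition are artifact-free).
    """
    if len(params_per_phase) != stack.n_phases:
        raise ValueError(
            f"expected {stack.n_phases} parameter entries, got {len(params_per_phase)}"
        )
    out = stack.data.copy()
    for p, params in enumerate(params_per_phase):
        if params is None:
            continue
        profile = make_profile(stack.geometry, params)
        out[:, :, p] = corrupt_image(stack.data[:, :, p], profile, stack.geometry)
    return PhaseStack(out, stack.geometry)
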