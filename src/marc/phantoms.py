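"""Synthetic multi-phase abdominal phantoms.

Clean ground-truth stacks for training and evaluating the artifact filter
without patient data. A phantom slice is a superposition of randomly
placed soft-edged ellipses (organ-like structures); the anatomy is frozen
across phases while per-structure intensities follow simple
piecewise-linear enhancement curves, emulating the contrast dynamics of a
pre-contrast + multi-arterial acquisition. An optional focal lesion — a
hard-edged disk with a user-specified 7-point enhancement curve — stands
in for hypervascular liver lesions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import DEFAULT_N_PHASES, AcquisitionGeometry, PhaseStack

__all__ = ["Lesion", "PhantomConfig", "generate_phantom", "lesion_mask"]


@dataclass(frozen=True)
class Lesion:
    """Focal lesion: hard-edged disk with its own enhancement curve.

    ``enhancement_curve`` holds one relative intensity in [0, 1] per phase;
    the added signal in phase p is ``amplitude * enhancement_curve[p]``
    inside the disk.
    """

    center: tuple  # (row, col), px
    radius: float  # px
    enhancement_curve: Sequence[float]
    amplitude: float = 0.2

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"lesion radius must be positive, got {self.radius}")
        curve = np.asarray(self.enhancement_curve, dtype=float)
        if curve.ndim != 1:
            raise ValueError("enhancement_curve must be 1-D")
        if np.any(curve < 0) or np.any(curve > 1):
            raise ValueError("enhancement_curve values must lie in [0, 1]")
        if not 0 < self.amplitude <= 1:
            raise ValueError(f"lesion amplitude must be in (0, 1], got {self.amplitude}")


@dataclass(frozen=True)
class PhantomConfig:
    matrix_rows: int = 256
    matrix_cols: int = 256
    n_phases: int = DEFAULT_N_PHASES
    n_ellipses: int = 12
    lesion: Optional[Lesion] = None
    intensity_range: tuple = (0.0, 1.0)
    #: relative spread of the background enhancement curves across phases
    phase_variation: float = 0.15
    #: gaussian edge softening of the background ellipses, px
    edge_sigma: float = 1.0
    #: amplitude of the static multiplicative texture field (organ texture);
    #: 0 disables it. Texture is shared across phases (it is anatomy).
    texture_amp: float = 0.35
    #: correlation length of the texture field, px
    texture_scale_px: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.matrix_rows <= 0 or self.matrix_cols <= 0:
            raise ValueError(
                f"matrix dimensions must be positive, got "
                f"{self.matrix_rows}x{self.matrix_cols}"
            )
        if self.n_phases < 1:
            raise ValueError(f"n_phases must be >= 1, got {self.n_phases}")
        if self.n_ellipses < 0:
            raise ValueError(f"n_ellipses must be >= 0, got {self.n_ellipses}")
        lo, hi = self.intensity_range
        if lo != 0.0 or not 0.0 < hi <= 1.0:
            raise ValueError(
                f"intensity_range must be (0, hi] with hi in (0, 1], got {self.intensity_range}"
            )
        if not 0.0 <= self.phase_variation < 1.0:
            raise ValueError(
                f"phase_variation must be in [0, 1), got {self.phase_variation}"
            )
        if self.texture_amp < 0:
            raise ValueError(f"texture_amp must be >= 0, got {self.texture_amp}")
        if self.lesion is not None:
            r, c = self.lesion.center
            rad = self.lesion.radius
            if len(self.lesion.enhancement_curve) != self.n_phases:
                raise ValueError(
                    f"lesion enhancement_curve has {len(self.lesion.enhancement_curve)} "
                    f"entries, expected n_phases={self.n_phases}"
                )
            if (
                r - rad < 0
                or c - rad < 0
                or r + rad > self.matrix_rows - 1
                or c + rad > self.matrix_cols - 1
            ):
                raise ValueError("lesion disk extends outside the image bounds")

    @property
    def geometry(self) -> AcquisitionGeometry:
        return AcquisitionGeometry(
            matrix_rows=self.matrix_rows, matrix_cols=self.matrix_cols
        )


def lesion_mask(config: PhantomConfig) -> np.ndarray:
    """Boolean disk mask of the configured lesion (False everywhere if none)."""
    mask = np.zeros((config.matrix_rows, config.matrix_cols), dtype=bool)
    if config.lesion is None:
        return mask
    rr, cc = np.ogrid[: config.matrix_rows, : config.matrix_cols]
    r0, c0 = config.lesion.center
    mask |= (rr - r0) ** 2 + (cc - c0) ** 2 <= config.lesion.radius ** 2
    return mask


def _ellipse(rows: int, cols: int, center, axes, angle) -> np.ndarray:
    rr, cc = np.ogrid[:rows, :cols]
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    return ((u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0).astype(float)


def _enhancement_curve(rng: np.random.Generator, n_phases: int, spread: float) -> np.ndarray:
    """Piecewise-linear per-structure enhancement multiplier, mean ~1."""
    n_knots = min(3, n_phases)
    knot_pos = np.linspace(0, n_phases - 1, n_knots)
    knot_val = 1.0 + rng.uniform(-spread, spread, size=n_knots)
    return np.interp(np.arange(n_phases), knot_pos, knot_val)


def generate_phantom(config: PhantomConfig) -> PhaseStack:
    """Generate a clean multi-phase phantom stack.

    Deterministic given ``config.seed``; all intensities lie in
    ``[0, intensity_range[1]]``. The thresholded support is identical
    across phases because anatomy is shared and enhancement curves are
    strictly positive for ``phase_variation < 1``.
    """
    rows, cols, n_phases = config.matrix_rows, config.matrix_cols, config.n_phases
    rng = np.random.default_rng(config.seed)
    hi = config.intensity_range[1]
    lesion_amp = config.lesion.amplitude * hi if config.lesion is not None else 0.0
    bg_peak = hi - lesion_amp

    stack = np.zeros((rows, cols, n_phases))
    if config.n_ellipses > 0:
        shapes = np.zeros((rows, cols, config.n_ellipses))
        curves = np.zeros((config.n_ellipses, n_phases))
        for i in range(config.n_ellipses):
            center = rng.uniform([0.15 * rows, 0.15 * cols], [0.85 * rows, 0.85 * cols])
            axes = rng.uniform(0.05, 0.3, size=2) * min(rows, cols)
            angle = rng.uniform(0, np.pi)
            base = rng.uniform(0.2, 1.0)
            mask = _ellipse(rows, cols, center, axes, angle)
            if config.edge_sigma > 0:
                mask = gaussian_filter(mask, config.edge_sigma)
            shapes[:, :, i] = base * mask
            curves[i] = _enhancement_curve(rng, n_phases, config.phase_variation)
        stack = shapes @ curves  # (rows, cols, n_phases)
        if config.texture_amp > 0:
            noise = gaussian_filter(rng.standard_normal((rows, cols)), config.texture_scale_px)
            span = np.abs(noise).max()
            if span > 0:
                noise /= span
            # strictly positive so the support mask survives across phases
            field = np.clip(1.0 + config.texture_amp * noise, 0.05, None)
            stack *= field[:, :, None]
        peak = stack.max()
        if peak > 0:
            stack *= bg_peak / peak

    if config.lesion is not None:
        disk = lesion_mask(config)
        curve = np.asarray(config.lesion.enhancement_curve, dtype=float)
        stack[disk] += lesion_amp * curve

    return PhaseStack(stack, config.geometry)
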