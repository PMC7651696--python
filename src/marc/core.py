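"""Core data containers shared across the pipeline.

Array layout convention (used everywhere): ``(row, col, phase)`` with row =
frequency-encode and col = phase-encode by default. A "stack" is one axial
slice observed at several temporal phases (pre-contrast plus arterial
phases); the phase axis is the channel axis the filter operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = ["AcquisitionGeometry", "PhaseStack", "DEFAULT_N_PHASES"]

#: pre-contrast phase + six arterial phases
DEFAULT_N_PHASES = 7

PhaseEncodeAxis = Literal["rows", "cols"]
Ordering = Literal["linear", "centric"]


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Cartesian 2D acquisition geometry.

    Maps physical motion (cm) to phase-encode pixel shifts and acquisition
    time. Defaults follow a multi-arterial liver protocol: 320x192 matrix,
    340 mm field of view, ~4 s per dynamic phase, centric phase-encode
    ordering (low spatial frequencies acquired first).

    Parameters
    ----------
    matrix_rows, matrix_cols : int
        Image matrix. The phase-encode axis (``phase_encode_axis``) selects
        which dimension is sampled sequentially in time.
    fov_mm : float
        Field of view along the phase-encode direction, millimetres.
    phase_encode_axis : {"rows", "cols"}
    readout_duration_s : float
        Wall-clock duration over which all phase-encode lines of one
        dynamic phase are acquired (temporal resolution).
    ordering : {"linear", "centric"}
        Order in which phase-encode lines are acquired: ``linear`` sweeps
        k_y monotonically, ``centric`` goes centre-out.
    """

    matrix_rows: int = 320
    matrix_cols: int = 192
    fov_mm: float = 340.0
    phase_encode_axis: PhaseEncodeAxis = "cols"
    readout_duration_s: float = 4.0
    ordering: Ordering = "centric"

    def __post_init__(self) -> None:
        if self.matrix_rows <= 0 or self.matrix_cols <= 0:
            raise ValueError(
                f"matrix dimensions must be positive, got "
                f"{self.matrix_rows}x{self.matrix_cols}"
            )
        if self.fov_mm <= 0:
            raise ValueError(f"fov_mm must be positive, got {self.fov_mm}")
        if self.readout_duration_s <= 0:
            raise ValueError(
                f"readout_duration_s must be positive, got {self.readout_duration_s}"
            )
        if self.phase_encode_axis not in ("rows", "cols"):
            raise ValueError(f"unknown phase_encode_axis {self.phase_encode_axis!r}")
        if self.ordering not in ("linear", "centric"):
            raise ValueError(f"unknown ordering {self.ordering!r}")

    @property
    def n_phase_encodes(self) -> int:
        """Number of phase-encode lines N."""
        return self.matrix_rows if self.phase_encode_axis == "rows" else self.matrix_cols

    @property
    def phase_encode_dim(self) -> int:
        """Array axis index (0 or 1) of the phase-encode direction."""
        return 0 if self.phase_encode_axis == "rows" else 1

    @property
    def pixel_mm(self) -> float:
        """Pixel pitch along the phase-encode direction, mm/px."""
        return self.fov_mm / self.n_phase_encodes

    def with_matrix(self, rows: int, cols: int) -> "AcquisitionGeometry":
        return replace(self, matrix_rows=rows, matrix_cols=cols)

    def to_dict(self) -> dict:
        return {
            "matrix_rows": self.matrix_rows,
            "matrix_cols": self.matrix_cols,
            "fov_mm": self.fov_mm,
            "phase_encode_axis": self.phase_encode_axis,
            "readout_duration_s": self.readout_duration_s,
            "ordering": self.ordering,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionGeometry":
        return cls(**d)


@dataclass
class PhaseStack:
    """One axial slice at ``n_phases`` temporal phases: array (rows, cols, phases).

    Magnitude data, hence non-negative; ``allow_negative`` relaxes the check
    for filter outputs, where subtracting the predicted artifact component
    may produce small negative values.
    """

    data: np.ndarray
    geometry: AcquisitionGeometry
    allow_negative: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"PhaseStack data must be 3-D (rows, cols, phases), got ndim={self.data.ndim}"
            )
        if self.data.shape[:2] != (self.geometry.matrix_rows, self.geometry.matrix_cols):
            raise ValueError(
                f"data spatial shape {self.data.shape[:2]} does not match geometry "
                f"({self.geometry.matrix_rows}, {self.geometry.matrix_cols})"
            )
        if not self.allow_negative and self.data.size and self.data.min() < 0:
            raise ValueError("magnitude stack contains negative values")

    @property
    def n_phases(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def copy(self) -> "PhaseStack":
        return PhaseStack(self.data.copy(), self.geometry, self.allow_negative)
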