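"""Paired noisy/residual patch datasets for residual training.

Training pairs are sliding-window crops from a corrupted stack (network
input) and from the artifact residual, corrupted minus clean (network
target). Both are normalised by the global maximum of the corrupted
stack, so the filtered image is recovered exactly as
``noisy*scale - residual*scale = clean``. Patches are 96x96x7 by default
and are stored in float32.

On-disk container: a single HDF5 file with datasets ``noisy``
(n, p, p, c), ``residual`` (same shape), ``scale`` (n,) and ``origin``
(n, 3; slice id, row, col), plus a format-version attribute.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence

import h5py
import numpy as np

from .core import PhaseStack

__all__ = [
    "PatchPair",
    "DatasetFormatError",
    "patch_count",
    "make_pairs",
    "save_dataset",
    "load_dataset",
    "stack_pairs",
]

DEFAULT_PATCH = 96
DEFAULT_STRIDE = 48  # 50% overlap

_FORMAT_VERSION = 1


class DatasetFormatError(ValueError):
    """Raised when a dataset file exists but is not a valid patch archive."""


@dataclass
class PatchPair:
    """Co-located corrupted and residual patches, with the divisor used."""

    noisy: np.ndarray  # (patch, patch, n_phases) float32, corrupted/scale
    residual: np.ndarray  # (corrupted - clean)/scale
    scale: float
    origin: tuple  # (slice id, row, col)

    def __post_init__(self) -> None:
        if self.noisy.shape != self.residual.shape:
            raise ValueError("noisy and residual patches must share a shape")
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")


def patch_count(rows: int, cols: int, patch: int, stride: int) -> int:
    """Closed-form number of sliding windows per slice."""
    return ((rows - patch) // stride + 1) * ((cols - patch) // stride + 1)


def make_pairs(
    clean: PhaseStack,
    corrupted: PhaseStack,
    patch: int = DEFAULT_PATCH,
    stride: int = DEFAULT_STRIDE,
    slice_id: int = 0,
) -> List[PatchPair]:
    """Crop co-located noisy/residual patch pairs from one stack pair.

    The normalisation scale is the global maximum of the corrupted stack
    (1.0 for an all-zero stack); every patch of the pair shares it.
    """
    if clean.shape != corrupted.shape:
        raise ValueError(
            f"clean and corrupted stacks differ in shape: {clean.shape} vs {corrupted.shape}"
        )
    rows, cols, _ = clean.shape
    if patch <= 0 or stride <= 0:
        raise ValueError("patch and stride must be positive")
    if patch > rows or patch > cols:
        raise ValueError(f"patch {patch} larger than image {rows}x{cols}")

    corr = corrupted.data.astype(np.float32)
    cln = clean.data.astype(np.float32)
    scale = float(corr.max())
    if scale <= 0:
        scale = 1.0
    noisy_full = corr / np.float32(scale)
    residual_full = (corr - cln) / np.float32(scale)

    pairs = []
    for r in range(0, rows - patch + 1, stride):
        for c in range(0, cols - patch + 1, stride):
            pairs.append(
                PatchPair(
                    noisy=noisy_full[r : r + patch, c : c + patch].copy(),
                    residual=residual_full[r : r + patch, c : c + patch].copy(),
                    scale=scale,
                    origin=(slice_id, r, c),
                )
            )
    return pairs


def stack_pairs(pairs: Sequence[PatchPair]) -> tuple:
    """Stack a pair list into (noisy, residual) arrays of shape (n, p, p, c)."""
    if not pairs:
        raise ValueError("empty pair list")
    noisy = np.stack([p.noisy for p in pairs])
    residual = np.stack([p.residual for p in pairs])
    return noisy, residual


def save_dataset(pairs: Sequence[PatchPair], path) -> None:
    if not pairs:
        raise ValueError("refusing to save an empty dataset")
    noisy, residual = stack_pairs(pairs)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        f.create_dataset("noisy", data=noisy.astype(np.float32))
        f.create_dataset("residual", data=residual.astype(np.float32))
        f.create_dataset("scale", data=np.array([p.scale for p in pairs], dtype=np.float64))
        f.create_dataset("origin", data=np.array([p.origin for p in pairs], dtype=np.int64))


def load_dataset(path) -> List[PatchPair]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such dataset file: {path}")
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise DatasetFormatError(f"{path} is not a readable patch archive: {exc}") from exc
    with f:
        for key in ("noisy", "residual", "scale", "origin"):
            if key not in f:
                raise DatasetFormatError(f"{path} is missing array {key!r}")
        noisy = f["noisy"][...]
        residual = f["residual"][...]
        scale = f["scale"][...]
        origin = f["origin"][...]
    if not (len(noisy) == len(residual) == len(scale) == len(origin)):
        raise DatasetFormatError(f"{path}: inconsistent array lengths")
    return [
        PatchPair(
            noisy=noisy[i],
            residual=residual[i],
            scale=float(scale[i]),
            origin=tuple(int(v) for v in origin[i]),
        )
        for i in range(len(noisy))
    ]
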