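"""Stack readers and writers: NIfTI and compressed array archives.

A stack is stored either as a 3-D NIfTI file (third axis = temporal
phase) with a JSON sidecar carrying the acquisition geometry (NIfTI-1 has
no fields for phase-encode ordering etc.), or as a single ``.npz``
archive embedding both payload and geometry. Both round-trip the array
payload losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import AcquisitionGeometry, PhaseStack

__all__ = ["read_stack", "write_stack", "sidecar_path"]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in _NIFTI_SUFFIXES:
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".geometry.json")
    return path.with_suffix(".geometry.json")


def _is_nifti(path: Path) -> bool:
    return any(path.name.endswith(s) for s in _NIFTI_SUFFIXES)


def write_stack(stack: PhaseStack, path) -> None:
    """Write a stack to NIfTI (+ geometry sidecar) or to a .npz archive."""
    path = Path(path)
    if _is_nifti(path):
        g = stack.geometry
        # isotropic in-plane pixel size from the FOV; phase axis unit-spaced
        pix = g.fov_mm / max(g.matrix_rows, g.matrix_cols)
        affine = np.diag([pix, pix, 1.0, 1.0])
        img = nib.Nifti1Image(stack.data.astype(np.float64), affine)
        img.header.set_xyzt_units(xyz="mm")
        nib.save(img, str(path))
        sidecar_path(path).write_text(json.dumps(stack.geometry.to_dict(), indent=2))
    elif path.suffix == ".npz":
        with open(path, "wb") as f:
            np.savez_compressed(
                f,
                data=stack.data,
                geometry=np.frombuffer(
                    json.dumps(stack.geometry.to_dict()).encode(), dtype=np.uint8
                ),
            )
    else:
        raise ValueError(f"unsupported stack format: {path.name} (use .nii, .nii.gz or .npz)")


def read_stack(path, expected_phases: int | None = None) -> PhaseStack:
    """Read a stack written by :func:`write_stack`.

    ``expected_phases`` (e.g. 7 for the filter pipeline) makes a phase
    count mismatch an explicit error reporting the found count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack file: {path}")
    if _is_nifti(path):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError(
                f"{path}: expected a 3-D volume (rows, cols, phases), got ndim={data.ndim}"
            )
        side = sidecar_path(path)
        if side.exists():
            geometry = AcquisitionGeometry.from_dict(json.loads(side.read_text()))
        else:
            geometry = AcquisitionGeometry(
                matrix_rows=data.shape[0], matrix_cols=data.shape[1]
            )
    elif path.suffix == ".npz":
        with np.load(path) as payload:
            data = payload["data"]
            geometry = AcquisitionGeometry.from_dict(
                json.loads(bytes(payload["geometry"]).decode())
            )
        if data.ndim != 3:
            raise ValueError(f"{path}: expected 3-D data, got ndim={data.ndim}")
    else:
        raise ValueError(f"unsupported stack format: {path.name}")
    if expected_phases is not None and data.shape[2] != expected_phases:
        raise ValueError(
            f"{path}: expected {expected_phases} phases, found {data.shape[2]}"
        )
    allow_negative = bool(data.size) and float(data.min()) < 0
    return PhaseStack(data, geometry, allow_negative=allow_negative)
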