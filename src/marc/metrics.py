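"""Full-reference image-quality metrics.

Quantitative stand-ins for reader-based artifact grading: peak
signal-to-noise ratio, structural similarity and residual artifact power.
PSNR uses the reference maximum as peak; SSIM is the standard Wang et al.
index (Gaussian-weighted 7x7 window, K1=0.01, K2=0.03) computed by
scikit-image, averaged over phases for 3-D stacks.
"""

from __future__ import annotations

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["psnr", "ssim", "artifact_power"]


def _check_shapes(reference: np.ndarray, test: np.ndarray) -> None:
    if reference.shape != test.shape:
        raise ValueError(
            f"shape mismatch: reference {reference.shape} vs test {test.shape}"
        )


def psnr(reference: np.ndarray, test: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    _check_shapes(reference, test)
    peak = reference.max()
    if peak <= 0:
        raise ValueError("reference image must have a positive maximum")
    mse = float(np.mean((reference - test) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(peak ** 2 / mse)


def ssim(reference: np.ndarray, test: np.ndarray, data_range: float | None = None) -> float:
    """Structural similarity in [-1, 1]; 1 for identical images.

    ``data_range`` defaults to the reference dynamic range, which makes
    the value invariant to a simultaneous rescaling of both inputs.
    """
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    _check_shapes(reference, test)
    if data_range is None:
        data_range = float(reference.max() - reference.min())
        if data_range == 0:
            data_range = 1.0
    kwargs = {"data_range": data_range}
    if reference.ndim == 3:
        kwargs["channel_axis"] = -1
    elif reference.ndim != 2:
        raise ValueError(f"expected a 2-D image or 3-D stack, got ndim={reference.ndim}")
    win = min(7, min(reference.shape[:2]))
    if win % 2 == 0:
        win -= 1
    kwargs["win_size"] = win
    return float(structural_similarity(reference, test, **kwargs))


def artifact_power(clean: np.ndarray, corrupted: np.ndarray) -> float:
    """Mean squared residual between clean and corrupted; 0 iff equal."""
    clean = np.asarray(clean, dtype=float)
    corrupted = np.asarray(corrupted, dtype=float)
    _check_shapes(clean, corrupted)
    return float(np.mean((corrupted - clean) ** 2))
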