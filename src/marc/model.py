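"""The residual artifact-extraction network.

A seven-layer, fully convolutional residual denoiser: each layer is a 3x3
same-padding convolution followed (except for the last layer) by batch
normalisation and a ReLU. The first and last layers carry seven filters —
one per temporal phase — and the hidden layers sixty-four. The network
maps a normalised 7-channel image (or 96x96x7 training patch) to its
predicted artifact component; the filtered image is input minus
prediction. The final layer has no batch-norm or activation because the
artifact residual is signed.

Because every layer is a stride-1 same-padding convolution, a trained
filter accepts any spatial size (e.g. full 320x192 slices) without
cropping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np

from .nn import BatchNorm2D, Conv2D, Network, ReLU

__all__ = [
    "NetworkSpec",
    "MarcFilter",
    "build",
    "predict_residual",
    "parameter_count",
    "save_filter",
    "load_filter",
]

STANDARD_CHANNELS = (7, 64, 64, 64, 64, 64, 7)


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of the residual filter.

    ``channels`` lists the output-filter count per layer; the standard
    pattern is 7 filters in the first and last layer and 64 in the five
    hidden ones. Alternative widths (e.g. a 64-filter first layer, or
    narrow nets for quick experiments) require ``allow_nonstandard``.
    """

    n_layers: int = 7
    kernel: Tuple[int, int] = (3, 3)
    channels: Tuple[int, ...] = STANDARD_CHANNELS
    input_channels: int = 7
    allow_nonstandard: bool = False

    def __post_init__(self) -> None:
        if self.n_layers != len(self.channels):
            raise ValueError(
                f"n_layers={self.n_layers} but channels has {len(self.channels)} entries"
            )
        if any(c <= 0 for c in self.channels):
            raise ValueError("all channel counts must be positive")
        if not self.allow_nonstandard:
            standard = (
                self.n_layers == 7
                and self.kernel == (3, 3)
                and self.channels == STANDARD_CHANNELS
                and self.input_channels == 7
            )
            if not standard:
                raise ValueError(
                    "non-standard architecture (expected 7 layers, 3x3 kernels, "
                    "channels 7/64/64/64/64/64/7); pass allow_nonstandard=True to override"
                )

    @property
    def batch_norm(self) -> Tuple[bool, ...]:
        """Per-layer batch-norm flags: on for all but the last layer."""
        return tuple(i < self.n_layers - 1 for i in range(self.n_layers))

    @property
    def activation(self) -> Tuple[bool, ...]:
        """Per-layer ReLU flags: on for all but the last layer."""
        return tuple(i < self.n_layers - 1 for i in range(self.n_layers))

    def to_dict(self) -> dict:
        return {
            "n_layers": self.n_layers,
            "kernel": list(self.kernel),
            "channels": list(self.channels),
            "input_channels": self.input_channels,
            "allow_nonstandard": self.allow_nonstandard,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        return cls(
            n_layers=d["n_layers"],
            kernel=tuple(d["kernel"]),
            channels=tuple(d["channels"]),
            input_channels=d["input_channels"],
            allow_nonstandard=d.get("allow_nonstandard", False),
        )


def parameter_count(spec: NetworkSpec) -> int:
    """Learnable parameters: conv weights+biases plus batch-norm gamma/beta."""
    kh, kw = spec.kernel
    total = 0
    c_in = spec.input_channels
    for i, c_out in enumerate(spec.channels):
        total += kh * kw * c_in * c_out + c_out
        if spec.batch_norm[i]:
            total += 2 * c_out
        c_in = c_out
    return total


@dataclass
class MarcFilter:
    """An (un)trained residual filter: architecture + parameter payload."""

    spec: NetworkSpec
    network: Network
    training_meta: dict = field(default_factory=dict)

    @property
    def n_parameters(self) -> int:
        return self.network.n_parameters

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Predicted artifact component of a normalised input.

        Accepts (H, W, C) or (B, H, W, C); inference mode (batch-norm uses
        running statistics), so the output is deterministic.
        """
        x = np.asarray(x, dtype=self.network.dtype)
        squeeze = x.ndim == 3
        if squeeze:
            x = x[None]
        if x.ndim != 4:
            raise ValueError(f"expected (H, W, C) or (B, H, W, C), got shape {x.shape}")
        if x.shape[-1] != self.spec.input_channels:
            raise ValueError(
                f"input has {x.shape[-1]} channels, filter expects {self.spec.input_channels}"
            )
        y = self.network.forward(x, training=False)
        return y[0] if squeeze else y


def build(
    spec: NetworkSpec, seed: int = 0, zero_last_layer: bool = False, dtype=np.float32
) -> MarcFilter:
    """Construct an untrained filter with seeded He-style initialisation.

    ``zero_last_layer`` starts the network at the identity denoiser
    (predicted residual identically zero), a useful baseline and a common
    initialisation for residual regression.
    """
    rng = np.random.default_rng(seed)
    layers = []
    c_in = spec.input_channels
    for i, c_out in enumerate(spec.channels):
        last = i == spec.n_layers - 1
        layers.append(
            Conv2D(
                c_in,
                c_out,
                kernel=spec.kernel,
                rng=rng,
                zero_init=last and zero_last_layer,
                compute_dx=i > 0,
                dtype=dtype,
            )
        )
        if spec.batch_norm[i]:
            layers.append(BatchNorm2D(c_out, dtype=dtype))
        if spec.activation[i]:
            layers.append(ReLU())
        c_in = c_out
    return MarcFilter(spec=spec, network=Network(layers))


def predict_residual(filt: MarcFilter, array: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`MarcFilter.predict`."""
    return filt.predict(array)


def save_filter(filt: MarcFilter, path) -> None:
    """Single-file weight format: .npz with a JSON spec header and all arrays."""
    arrays = filt.network.state_arrays()
    header = json.dumps(
        {"spec": filt.spec.to_dict(), "training_meta": filt.training_meta}
    )
    with open(path, "wb") as f:  # keep the exact filename (np.savez appends .npz)
        np.savez(f, __header__=np.frombuffer(header.encode(), dtype=np.uint8), **arrays)


def load_filter(path) -> MarcFilter:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such weight file: {path}")
    with np.load(path) as payload:
        if "__header__" not in payload:
            raise ValueError(f"{path} is not a filter weight file (missing header)")
        header = json.loads(bytes(payload["__header__"]).decode())
        spec = NetworkSpec.from_dict(header["spec"])
        filt = build(spec, seed=0)
        filt.training_meta = header.get("training_meta", {})
        filt.network.load_state_arrays({k: payload[k] for k in payload.files if k != "__header__"})
    return filt
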