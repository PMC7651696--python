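"""Training on patch pairs and whole-stack inference.

The filter is trained by residual learning: minimise the mean squared
error between the predicted and the true artifact patches. At inference
the stack is normalised by its own maximum, the residual is predicted,
and the output is ``input - scale * residual(input / scale)`` — an exact
algebraic inversion of the training normalisation, so a filter that
predicts the true residual recovers the clean stack.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .core import PhaseStack
from .dataset import PatchPair, stack_pairs
from .model import MarcFilter
from .nn import Adam, SGD, mse_loss

__all__ = ["TrainConfig", "TrainingDiverged", "train", "denoise"]


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"  # "adam" (adaptive moment) or "sgd"
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be > 0, got {self.learning_rate}")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError(f"val_fraction must be in [0, 1), got {self.val_fraction}")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


def _eval_loss(filt: MarcFilter, x: np.ndarray, y: np.ndarray, batch: int) -> float:
    total, n = 0.0, 0
    for i in range(0, len(x), batch):
        pred = filt.network.forward(x[i : i + batch], training=False)
        total += float(np.sum((pred.astype(np.float64) - y[i : i + batch]) ** 2))
        n += pred.size
    return total / n


def train(
    filt: MarcFilter, pairs: Sequence[PatchPair], config: TrainConfig
) -> Tuple[MarcFilter, dict]:
    """Train in place on a pair dataset; returns the filter and its history.

    Deterministic given ``config.seed`` (fixed validation split and epoch
    shuffling). History records per-epoch mean training loss and the loss
    on the held-out validation fraction (per-step losses are kept too).
    """
    if not pairs:
        raise ValueError("cannot train on an empty dataset")
    noisy, residual = stack_pairs(pairs)
    if noisy.shape[-1] != filt.spec.input_channels:
        raise ValueError(
            f"dataset has {noisy.shape[-1]} channels, filter expects "
            f"{filt.spec.input_channels}"
        )
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(noisy))
    n_val = int(round(config.val_fraction * len(noisy)))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        raise ValueError("validation fraction leaves no training samples")
    x_tr, y_tr = noisy[train_idx], residual[train_idx]
    x_va, y_va = noisy[val_idx], residual[val_idx]

    if config.optimizer == "adam":
        opt = Adam(filt.network, lr=config.learning_rate)
    else:
        opt = SGD(filt.network, lr=config.learning_rate)

    history = {"train_loss": [], "val_loss": [], "step_loss": []}
    for epoch in range(config.epochs):
        perm = rng.permutation(len(x_tr))
        epoch_losses = []
        for i in range(0, len(perm), config.batch_size):
            idx = perm[i : i + config.batch_size]
            pred = filt.network.forward(x_tr[idx], training=True)
            loss, grad = mse_loss(pred, y_tr[idx])
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite training loss at epoch {epoch}, step {i // config.batch_size}"
                )
            filt.network.backward(grad)
            opt.step()
            epoch_losses.append(loss)
            history["step_loss"].append(loss)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(
            _eval_loss(filt, x_va, y_va, config.batch_size) if n_val else float("nan")
        )

    filt.training_meta = {
        "seed": config.seed,
        "epochs": config.epochs,
        "batch_size": config.batch_size,
        "learning_rate": config.learning_rate,
        "optimizer": config.optimizer,
        "n_pairs": len(pairs),
        "train_loss": history["train_loss"],
        "val_loss": history["val_loss"],
    }
    return filt, history


def denoise(filt: MarcFilter, stack: PhaseStack, clip_zero: bool = False) -> PhaseStack:
    """Apply the filter to a whole stack: output = input - scale * residual.

    The stack is normalised by its own maximum (the training-time scale is
    not transportable to unseen images). An all-zero stack is returned
    unchanged. ``clip_zero`` clamps negative outputs for display.
    """
    if stack.n_phases != filt.spec.input_channels:
        raise ValueError(
            f"stack has {stack.n_phases} phases, filter expects {filt.spec.input_channels}"
        )
    scale = float(stack.data.max())
    if scale <= 0:
        return stack.copy()
    residual = filt.predict((stack.data / scale).astype(np.float32))
    out = stack.data - scale * residual.astype(np.float64)
    if clip_zero:
        out = np.maximum(out, 0.0)
    return PhaseStack(out, stack.geometry, allow_negative=not clip_zero)
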