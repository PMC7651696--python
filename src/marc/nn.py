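"""Minimal CPU convolutional-network engine (numpy, NHWC).

Implements exactly what the artifact filter needs: same-padding stride-1
convolutions, batch normalisation, ReLU, mean squared error, and Adam /
SGD optimisers. A k_h x k_w convolution is computed as k_h*k_w shifted
BLAS matmuls, which avoids the memory blow-up of im2col and keeps the
inner loops inside BLAS. Forward and backward passes follow closed-form
gradients and are verified against finite differences in the test suite.
Everything is seeded, so training is bit-reproducible on a platform.

Layers default to float32; pass ``dtype=np.float64`` for high-precision
checks.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np

__all__ = ["Conv2D", "BatchNorm2D", "ReLU", "Network", "Adam", "SGD", "mse_loss"]

F32 = np.float32


class Layer:
    def params(self) -> Dict[str, np.ndarray]:
        return {}

    def grads(self) -> Dict[str, np.ndarray]:
        return {}

    def state(self) -> Dict[str, np.ndarray]:
        """Non-learnable buffers (e.g. batch-norm running statistics)."""
        return {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Same-padding stride-1 convolution. Weights: (kh, kw, c_in, c_out).

    ``compute_dx=False`` skips the input gradient (valid for the first
    layer of a network, where it is never used).
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: Tuple[int, int] = (3, 3),
        rng: Optional[np.random.Generator] = None,
        zero_init: bool = False,
        compute_dx: bool = True,
        dtype=F32,
    ):
        self.c_in, self.c_out = c_in, c_out
        self.kh, self.kw = kernel
        if self.kh % 2 == 0 or self.kw % 2 == 0:
            raise ValueError("kernel sides must be odd for same padding")
        self.compute_dx = compute_dx
        if zero_init:
            w = np.zeros((self.kh, self.kw, c_in, c_out))
        else:
            rng = rng or np.random.default_rng()
            fan_in = c_in * self.kh * self.kw
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(self.kh, self.kw, c_in, c_out))
        self.w = w.astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols: Optional[np.ndarray] = None
        self._in_shape: Optional[Tuple[int, ...]] = None
        # persistent scratch (large allocations are expensive on 1 CPU)
        self._scratch: Dict[str, np.ndarray] = {}

    def _buf(self, name: str, shape: Tuple[int, ...], dtype) -> np.ndarray:
        buf = self._scratch.get(name)
        if buf is None or buf.shape != shape or buf.dtype != dtype:
            buf = np.empty(shape, dtype)
            self._scratch[name] = buf
        return buf

    @property
    def n_parameters(self) -> int:
        return self.w.size + self.b.size

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        """(B,H,W,C) -> (B*H*W, kh*kw*C), tap-major to match w.reshape(-1, c_out)."""
        b, h, w_, c = x.shape
        ph, pw = self.kh // 2, self.kw // 2
        xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        cols = self._buf("cols", (b, h, w_, self.kh * self.kw, c), x.dtype)
        for ki in range(self.kh):
            for kj in range(self.kw):
                cols[:, :, :, ki * self.kw + kj, :] = xp[:, ki : ki + h, kj : kj + w_, :]
        return cols.reshape(b * h * w_, -1)

    def forward(self, x, training):
        b, h, w_, _ = x.shape
        cols = self._im2col(x)
        if training:
            self._cols = cols
            self._in_shape = x.shape
        y = np.matmul(cols, self.w.reshape(-1, self.c_out))
        y += self.b
        return y.reshape(b, h, w_, self.c_out)

    def backward(self, dy):
        assert self._cols is not None, "backward before forward(training=True)"
        b, h, w_, _ = self._in_shape
        dy_flat = dy.reshape(-1, self.c_out)
        np.matmul(self._cols.T, dy_flat, out=self.dw.reshape(-1, self.c_out))
        self.db[...] = dy_flat.sum(axis=0)
        self._cols = None
        if not self.compute_dx:
            return None
        # scatter-add the column gradient back to (padded) input positions
        dcols = self._buf("dcols", (b * h * w_, self.kh * self.kw * self.c_in), dy.dtype)
        np.matmul(dy_flat, self.w.reshape(-1, self.c_out).T, out=dcols)
        dcols = dcols.reshape(b, h, w_, self.kh * self.kw, self.c_in)
        ph, pw = self.kh // 2, self.kw // 2
        dxp = self._buf("dxp", (b, h + 2 * ph, w_ + 2 * pw, self.c_in), dy.dtype)
        dxp[...] = 0.0
        for ki in range(self.kh):
            for kj in range(self.kw):
                dxp[:, ki : ki + h, kj : kj + w_, :] += dcols[:, :, :, ki * self.kw + kj, :]
        return dxp[:, ph : ph + h, pw : pw + w_, :]


class BatchNorm2D(Layer):
    """Per-channel batch normalisation over (batch, height, width)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5, dtype=F32):
        self.gamma = np.ones(c, dtype=dtype)
        self.beta = np.zeros(c, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    @property
    def n_parameters(self) -> int:
        return self.gamma.size + self.beta.size

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x, training):
        # the training path mutates x in place; x is always a fresh
        # intermediate (the preceding convolution's output)
        axes = (0, 1, 2)
        if training:
            mean = x.mean(axis=axes)
            var = np.einsum("bhwc,bhwc->c", x, x) / (x.size / x.shape[-1]) - mean**2
            var = np.maximum(var, 0.0)
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mean
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        ivar = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        if not training:
            return (x - mean.astype(x.dtype)) * ivar * self.gamma + self.beta
        x -= mean.astype(x.dtype)
        x *= ivar
        self._cache = (x, ivar)  # x is now xhat
        y = x * self.gamma
        y += self.beta
        return y

    def backward(self, dy):
        xhat, ivar = self._cache
        self._cache = None
        n = dy.size / dy.shape[-1]
        self.dgamma[...] = np.einsum("bhwc,bhwc->c", dy, xhat)
        self.dbeta[...] = dy.sum(axis=(0, 1, 2))
        # with dxhat = dy*gamma, the channel mean of dxhat and its xhat
        # projection follow from dbeta and dgamma — no extra reductions
        dy = dy * self.gamma
        xhat *= (self.dgamma * self.gamma / n).astype(dy.dtype)
        dy -= (self.dbeta * self.gamma / n).astype(dy.dtype)
        dy -= xhat
        dy *= ivar
        return dy


class ReLU(Layer):
    n_parameters = 0

    def __init__(self):
        self._mask = None

    def forward(self, x, training):
        if training:
            self._mask = x > 0
            x *= self._mask  # in place: x is a fresh intermediate
            return x
        return np.maximum(x, 0)

    def backward(self, dy):
        dy *= self._mask
        self._mask = None
        return dy


class Network:
    """A plain sequence of layers with manual forward/backward."""

    def __init__(self, layers: List[Layer]):
        self.layers = layers

    @property
    def n_parameters(self) -> int:
        return sum(getattr(l, "n_parameters", 0) for l in self.layers)

    @property
    def dtype(self):
        for layer in self.layers:
            for arr in layer.params().values():
                return arr.dtype
        return F32

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> Optional[np.ndarray]:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self) -> List[Tuple[str, Dict[str, np.ndarray]]]:
        return [(f"layer{i}", layer.params()) for i, layer in enumerate(self.layers)]

    def gradients(self) -> List[Tuple[str, Dict[str, np.ndarray]]]:
        return [(f"layer{i}", layer.grads()) for i, layer in enumerate(self.layers)]

    def state_arrays(self) -> Dict[str, np.ndarray]:
        """Flat name -> array map of all parameters and buffers."""
        out = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params().items():
                out[f"layer{i}.{name}"] = arr
            for name, arr in layer.state().items():
                out[f"layer{i}.{name}"] = arr
        return out

    def load_state_arrays(self, arrays: Dict[str, np.ndarray]) -> None:
        own = self.state_arrays()
        missing = set(own) - set(arrays)
        if missing:
            raise ValueError(f"weight payload is missing arrays: {sorted(missing)}")
        for name, arr in own.items():
            src = np.asarray(arrays[name])
            if src.shape != arr.shape:
                raise ValueError(
                    f"{name}: shape {src.shape} does not match expected {arr.shape}"
                )
            arr[...] = src


def mse_loss(pred: np.ndarray, target: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean squared error and its gradient w.r.t. ``pred``."""
    diff = pred - target
    loss = float(np.mean(diff.astype(np.float64) ** 2))
    grad = (2.0 / diff.size) * diff
    return loss, grad.astype(pred.dtype, copy=False)


class Adam:
    """Adam with bias correction; operates in-place on network parameters."""

    def __init__(self, network: Network, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.network = network
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p) for k, p in dict_flat(network.parameters()).items()}
        self.v = {k: np.zeros_like(p) for k, p in dict_flat(network.parameters()).items()}

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        params = dict_flat(self.network.parameters())
        grads = dict_flat(self.network.gradients())
        for key, p in params.items():
            g = grads[key]
            m = self.m[key]
            v = self.v[key]
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)


class SGD:
    """Plain stochastic gradient descent."""

    def __init__(self, network: Network, lr: float = 1e-3):
        self.network = network
        self.lr = lr

    def step(self) -> None:
        params = dict_flat(self.network.parameters())
        grads = dict_flat(self.network.gradients())
        for key, p in params.items():
            p -= (self.lr * grads[key]).astype(p.dtype)


def dict_flat(named: List[Tuple[str, Dict[str, np.ndarray]]]) -> Dict[str, np.ndarray]:
    return {f"{lname}.{pname}": arr for lname, d in named for pname, arr in d.items()}
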