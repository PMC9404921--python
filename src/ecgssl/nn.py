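"""Minimal NumPy neural-network engine for 1-D convolutional models.

Implements exactly the layer vocabulary the ECG encoder needs — 1-D "same"
convolution, ReLU, non-overlapping max-pooling, inverted dropout, dense
layers (optionally applied per time position) with L2 weight penalties,
flatten — plus reverse-mode gradients and an Adam optimizer.  Shapes follow
the channels-last convention ``(batch, length, channels)``.

Weight initialization is Glorot-uniform and deterministic given a seed, so
two builds from the same configuration are bit-identical.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1D",
    "ReLU",
    "MaxPool1D",
    "Dropout",
    "Dense",
    "TimeDense",
    "Flatten",
    "Sequential",
    "Adam",
    "softmax",
]


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - np.max(z, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


DTYPE = np.float32  # network compute precision; loss oracles stay float64


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Layer:
    """Base layer: subclasses fill ``params``/``grads`` dicts by name."""

    name = "layer"

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, train=False, rng=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - abstract
        raise NotImplementedError

    def l2_penalty(self) -> float:
        return 0.0


class Conv1D(Layer):
    """1-D convolution, stride 1, "same" zero padding, channels last."""

    def __init__(self, in_channels: int, filters: int, kernel: int, rng: np.random.Generator, name: str):
        super().__init__()
        self.name = name
        self.kernel = kernel
        self.in_channels = in_channels
        self.filters = filters
        fan_in, fan_out = kernel * in_channels, kernel * filters
        self.params["W"] = _glorot(rng, (in_channels, kernel, filters), fan_in, fan_out)
        self.params["b"] = np.zeros(filters, dtype=DTYPE)
        self.pad_left = (kernel - 1) // 2
        self.pad_right = kernel - 1 - self.pad_left

    def forward(self, x, train=False, rng=None):
        B, L, C = x.shape
        if C != self.in_channels:
            raise ValueError(f"{self.name}: expected {self.in_channels} channels, got {C}")
        xp = np.pad(x, ((0, 0), (self.pad_left, self.pad_right), (0, 0)))
        # patches[b, l, c, t] = x_padded[b, l + t, c]
        patches = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=1)
        self._patches = patches.reshape(B, L, C * self.kernel)
        Wf = self.params["W"].reshape(C * self.kernel, self.filters)
        self._shape_in = (B, L, C)
        return self._patches @ Wf + self.params["b"]

    def backward(self, dout):
        B, L, C = self._shape_in
        k = self.kernel
        Wf = self.params["W"].reshape(C * k, self.filters)
        self.grads["W"] = (
            self._patches.reshape(-1, C * k).T @ dout.reshape(-1, self.filters)
        ).reshape(self.params["W"].shape)
        self.grads["b"] = dout.sum(axis=(0, 1))
        dpatch = (dout @ Wf.T).reshape(B, L, C, k)
        dxp = np.zeros((B, L + k - 1, C), dtype=DTYPE)
        for t in range(k):
            dxp[:, t : t + L, :] += dpatch[:, :, :, t]
        return dxp[:, self.pad_left : self.pad_left + L, :]


class ReLU(Layer):
    name = "relu"

    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling along time; trailing remainder dropped."""

    def __init__(self, pool: int, name: str = "pool"):
        super().__init__()
        self.pool = pool
        self.name = name

    def forward(self, x, train=False, rng=None):
        B, L, C = x.shape
        Lp = L // self.pool
        if Lp == 0:
            raise ValueError(f"{self.name}: length {L} shorter than pool {self.pool}")
        xr = x[:, : Lp * self.pool, :].reshape(B, Lp, self.pool, C)
        self._argmax = xr.argmax(axis=2)
        self._shape_in = (B, L, C)
        return xr.max(axis=2)

    def backward(self, dout):
        B, L, C = self._shape_in
        Lp = L // self.pool
        dxr = np.zeros((B, Lp, self.pool, C), dtype=DTYPE)
        bi, li, ci = np.ogrid[:B, :Lp, :C]
        dxr[bi, li, self._argmax, ci] = dout
        dx = np.zeros((B, L, C), dtype=DTYPE)
        dx[:, : Lp * self.pool, :] = dxr.reshape(B, Lp * self.pool, C)
        return dx


class Dropout(Layer):
    """Inverted dropout: active only in train mode, identity in eval mode."""

    def __init__(self, rate: float, name: str = "dropout"):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.name = name

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in train mode needs an rng")
        self._mask = ((rng.random(x.shape) >= self.rate) / (1.0 - self.rate)).astype(DTYPE)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class TimeDense(Layer):
    """Dense layer applied independently at every time position.

    Equivalent to a width-1 convolution with ``units`` filters; carries the
    encoder's L2 weight penalty.
    """

    def __init__(self, in_channels: int, units: int, rng: np.random.Generator, l2: float = 0.0, name: str = "timedense"):
        super().__init__()
        self.name = name
        self.l2 = l2
        self.params["W"] = _glorot(rng, (in_channels, units), in_channels, units)
        self.params["b"] = np.zeros(units, dtype=DTYPE)

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        W = self.params["W"]
        self.grads["W"] = (
            self._x.reshape(-1, W.shape[0]).T @ dout.reshape(-1, W.shape[1])
            + 2.0 * self.l2 * W
        )
        self.grads["b"] = dout.sum(axis=tuple(range(dout.ndim - 1)))
        return dout @ W.T

    def l2_penalty(self) -> float:
        return float(self.l2 * np.sum(self.params["W"] ** 2))


class Dense(TimeDense):
    """Dense layer over flat feature vectors (B, F) -> (B, units)."""

    def __init__(self, in_features: int, units: int, rng: np.random.Generator, l2: float = 0.0, name: str = "dense"):
        super().__init__(in_features, units, rng, l2=l2, name=name)


class Flatten(Layer):
    name = "flatten"

    def forward(self, x, train=False, rng=None):
        self._shape_in = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape_in)


class Sequential:
    """An ordered layer stack with shared forward/backward plumbing."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def l2_penalty(self) -> float:
        return sum(layer.l2_penalty() for layer in self.layers)

    def named_params(self) -> list[tuple[str, np.ndarray]]:
        out = []
        for layer in self.layers:
            for pname, arr in layer.params.items():
                out.append((f"{layer.name}/{pname}", arr))
        return out

    def named_grads(self) -> list[tuple[str, np.ndarray]]:
        out = []
        for layer in self.layers:
            for pname, arr in layer.grads.items():
                out.append((f"{layer.name}/{pname}", arr))
        return out

    def get_weights(self) -> dict[str, np.ndarray]:
        return {name: arr.copy() for name, arr in self.named_params()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for layer in self.layers:
            for pname in layer.params:
                key = f"{layer.name}/{pname}"
                if key not in weights:
                    raise KeyError(f"missing weight {key}")
                src = np.asarray(weights[key])
                if src.shape != layer.params[pname].shape:
                    raise ValueError(
                        f"shape mismatch for {key}: "
                        f"{src.shape} vs {layer.params[pname].shape}"
                    )
                layer.params[pname] = src.astype(DTYPE)


class Adam:
    """Adam optimizer over one or more Sequential models."""

    def __init__(self, models: list[Sequential], lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.models = models
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        i = 0
        for model in self.models:
            for layer in model.layers:
                for pname, p in layer.params.items():
                    g = layer.grads[pname]
                    if i not in self._m:
                        self._m[i] = np.zeros_like(p)
                        self._v[i] = np.zeros_like(p)
                    self._m[i] = self.beta1 * self._m[i] + (1 - self.beta1) * g
                    self._v[i] = self.beta2 * self._v[i] + (1 - self.beta2) * g**2
                    p -= self.lr * (self._m[i] / b1t) / (np.sqrt(self._v[i] / b2t) + self.eps)
                    i += 1
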