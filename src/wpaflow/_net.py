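"""Minimal CPU convolutional network (numpy).

Just enough machinery for the four-class aggregate classifier: 3×3 same-pad
convolutions via im2col, 2×2 max-pooling, dense layers, ReLU, softmax
cross-entropy, and Adam.  Shapes follow the (batch, channels, height, width)
convention.  All randomness goes through an injected Generator.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B,C,H,W) -> (B*H*W, C*k*k) patches with same padding."""
    b, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))       # (B,C,H,W,k,k)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * k * k)


class Conv2D:
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in)).astype(np.float64)
        self.b = np.zeros(c_out)
        self.k, self.c_in, self.c_out = k, c_in, c_out

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        self._cols = _im2col(x, self.k)
        b, _, h, w = x.shape
        out = self._cols @ self.W.T + self.b
        return out.reshape(b, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        k, p = self.k, self.k // 2
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, self.c_out)
        self.dW = dflat.T @ self._cols
        self.db = dflat.sum(axis=0)
        dcols = (dflat @ self.W).reshape(b, h, w, c, k, k)
        dxp = np.zeros((b, c, h + 2 * p, w + 2 * p))
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di:di + h, dj:dj + w] += dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w]

    @property
    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class MaxPool2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        dxr = np.zeros((b, c, h // 2, w // 2, 4))
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        return dxr.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h, w)

    params: list = []


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    params: list = []


class Flatten:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)

    params: list = []


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in))
        self.b = np.zeros(n_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = dout.T @ self._x
        self.db = dout.sum(axis=0)
        return dout @ self.W

    @property
    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Sequential:
    def __init__(self, layers):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def parameter_slots(self):
        for layer in self.layers:
            for name, value, grad_name in layer.params:
                yield layer, name, value, grad_name

    def state_arrays(self) -> list[np.ndarray]:
        return [value for _, _, value, _ in self.parameter_slots()]

    def load_state(self, arrays: list[np.ndarray]) -> None:
        slots = list(self.parameter_slots())
        if len(arrays) != len(slots):
            raise ValueError("parameter count mismatch when loading model state")
        for (layer, name, value, _), arr in zip(slots, arrays):
            if value.shape != arr.shape:
                raise ValueError(f"shape mismatch for {name}: {value.shape} vs {arr.shape}")
            setattr(layer, name, arr.copy())


class Adam:
    def __init__(self, net: Sequential, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net, self.lr, self.beta1, self.beta2, self.eps = net, lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(v) for v in net.state_arrays()]
        self.v = [np.zeros_like(v) for v in net.state_arrays()]

    def step(self) -> None:
        self.t += 1
        for i, (layer, name, value, grad_name) in enumerate(self.net.parameter_slots()):
            g = getattr(layer, grad_name)
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / (1 - self.beta1 ** self.t)
            vhat = self.v[i] / (1 - self.beta2 ** self.t)
            setattr(layer, name, value - self.lr * mhat / (np.sqrt(vhat) + self.eps))
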