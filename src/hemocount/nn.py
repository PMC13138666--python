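"""Minimal feed-forward network engine on numpy.

Implements exactly the pieces the ROI classifier needs — valid-mode 2-D
convolution (im2col + GEMM), 2x2 max pooling, batch normalization, dropout,
dense layers, ReLU, softmax cross-entropy and the Adam optimizer — in
float32, with all randomness (initialization, dropout) drawn from generators
passed in explicitly.  Gradients are exact (verified against finite
differences in the test suite).

Array layout is channels-last: images ``(N, H, W, C)``, features ``(N, F)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class: parameters in ``params``, matching gradients in ``grads``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Valid-mode convolution with a square kernel, He-initialized."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.k = kernel
        self.cin = in_channels
        self.cout = out_channels
        fan_in = kernel * kernel * in_channels
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), (fan_in, out_channels)
        ).astype(np.float32)
        self.params["b"] = np.zeros(out_channels, dtype=np.float32)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        # (N, Ho, Wo, k, k, C) -> (N*Ho*Wo, k*k*C)
        win = sliding_window_view(x, (self.k, self.k), axis=(1, 2))
        win = np.ascontiguousarray(np.moveaxis(win, 3, -1))  # (N,Ho,Wo,k,k,C)
        self._out_shape = win.shape[:3]
        return win.reshape(-1, self.k * self.k * self.cin)

    def forward(self, x, training=False, rng=None):
        x = np.ascontiguousarray(x, dtype=np.float32)
        self._in_shape = x.shape
        cols = self._im2col(x)
        self._cols = cols
        y = cols @ self.params["W"] + self.params["b"]
        n, ho, wo = self._out_shape
        return y.reshape(n, ho, wo, self.cout)

    def backward(self, grad):
        n, ho, wo, _ = grad.shape
        g = grad.reshape(-1, self.cout).astype(np.float32)
        self.grads["W"] = self._cols.T @ g
        self.grads["b"] = g.sum(axis=0)
        dcols = (g @ self.params["W"].T).reshape(n, ho, wo, self.k, self.k, self.cin)
        dx = np.zeros(self._in_shape, dtype=np.float32)
        for dy in range(self.k):
            for dx_ in range(self.k):
                dx[:, dy : dy + ho, dx_ : dx_ + wo, :] += dcols[:, :, :, dy, dx_, :]
        self._cols = None
        return dx


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; trailing odd rows/cols are dropped."""

    def forward(self, x, training=False, rng=None):
        n, h, w, c = x.shape
        self._orig_shape = x.shape
        ho, wo = h // 2, w // 2
        self._core_shape = (n, ho * 2, wo * 2, c)
        win = (x[:, : ho * 2, : wo * 2, :]
               .reshape(n, ho, 2, wo, 2, c)
               .transpose(0, 1, 3, 5, 2, 4)
               .reshape(n, ho, wo, c, 4))
        self._argmax = win.argmax(axis=-1)  # one winner per window
        return np.take_along_axis(win, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        n, ho, wo, c = grad.shape
        dwin = np.zeros((n, ho, wo, c, 4), dtype=np.float32)
        np.put_along_axis(dwin, self._argmax[..., None],
                          grad[..., None].astype(np.float32), axis=-1)
        dx_core = (dwin.reshape(n, ho, wo, c, 2, 2)
                   .transpose(0, 1, 4, 2, 5, 3)
                   .reshape(self._core_shape))
        if self._core_shape == self._orig_shape:
            return dx_core
        dx = np.zeros(self._orig_shape, dtype=np.float32)
        dx[:, : self._core_shape[1], : self._core_shape[2], :] = dx_core
        return dx


class BatchNorm(Layer):
    """Per-feature (dense) or per-channel (conv) batch normalization."""

    def __init__(self, n_features: int, momentum: float = 0.9,
                 eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(n_features, dtype=np.float32)
        self.params["beta"] = np.zeros(n_features, dtype=np.float32)
        self.running_mean = np.zeros(n_features, dtype=np.float32)
        self.running_var = np.ones(n_features, dtype=np.float32)

    def forward(self, x, training=False, rng=None):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(np.float32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps).astype(np.float32)
        self._xhat = ((x - mean) / self._std).astype(np.float32)
        self._axes = axes
        self._m = x.size // x.shape[-1]
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, grad):
        axes = self._axes
        self.grads["gamma"] = (grad * self._xhat).sum(axis=axes)
        self.grads["beta"] = grad.sum(axis=axes)
        g = grad * self.params["gamma"]
        m = self._m
        dx = (g - g.mean(axis=axes)
              - self._xhat * (g * self._xhat).sum(axis=axes) / m) / self._std
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / n_in), (n_in, n_out)
        ).astype(np.float32)
        self.params["b"] = np.zeros(n_out, dtype=np.float32)

    def forward(self, x, training=False, rng=None):
        self._x = x.astype(np.float32)
        return self._x @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        self.grads["W"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return (grad @ self.params["W"].T).astype(np.float32)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-(onehot * np.log(p + 1e-12)).sum() / n)
    return loss, ((p - onehot) / n).astype(np.float32)


class Sequential:
    """Ordered layer stack with shared forward/backward plumbing."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            out.append(softmax(self.forward(x[i : i + batch_size], training=False)))
        return np.concatenate(out, axis=0)

    # -- (de)serialization ----------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for name, value in layer.params.items():
                state[f"layer{i}.{name}"] = value
            if isinstance(layer, BatchNorm):
                state[f"layer{i}.running_mean"] = layer.running_mean
                state[f"layer{i}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = np.asarray(state[f"layer{i}.{name}"],
                                                dtype=np.float32)
            if isinstance(layer, BatchNorm):
                layer.running_mean = np.asarray(state[f"layer{i}.running_mean"],
                                                dtype=np.float32)
                layer.running_var = np.asarray(state[f"layer{i}.running_var"],
                                               dtype=np.float32)


class Adam:
    """Adaptive-moment optimizer over a Sequential's parameters."""

    def __init__(self, model: Sequential, learning_rate: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7) -> None:
        self.model = model
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in self._iter_params()}
        self.v = {k: np.zeros_like(v) for k, v in self._iter_params()}

    def _iter_params(self):
        for i, layer in enumerate(self.model.layers):
            for name, value in layer.params.items():
                yield f"{i}.{name}", value

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.beta2**self.t) / (1 - self.beta1**self.t)
        for i, layer in enumerate(self.model.layers):
            for name in layer.params:
                key = f"{i}.{name}"
                g = layer.grads[name].astype(np.float32)
                self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
                self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g * g
                layer.params[name] -= lr_t * self.m[key] / (
                    np.sqrt(self.v[key]) + self.eps
                )
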