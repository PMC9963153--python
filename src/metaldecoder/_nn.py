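"""Minimal NumPy neural-network engine for the 1-D CNN models.

Implements exactly the layer set the concentration regressor and the
binary transfer model need — 1-D convolution with "same" padding, ReLU,
batch normalization, inverted dropout, flatten, dense with optional L2
penalty, sigmoid — plus Adam and reverse-mode gradients.  Inputs are
(batch, channels, length) arrays; all randomness (weight init, dropout,
shuffling) flows through a single ``numpy.random.Generator`` so training is
bit-reproducible for a fixed seed on a single thread.

Gradients are exact (validated by finite differences in the test suite),
not approximations; the engine is small because the model is small: input
length 22, a few thousand parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Layer",
    "Conv1D",
    "ReLU",
    "BatchNorm1D",
    "Dropout",
    "Flatten",
    "Dense",
    "Sigmoid",
    "Network",
    "Adam",
    "mse_loss",
    "bce_loss",
]


class Layer:
    """Base layer: parameter dict, gradient dict, trainable flag."""

    trainable = True

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def l2_penalty(self) -> float:
        return 0.0


class Conv1D(Layer):
    """1-D convolution, stride 1, "same" zero padding, He-initialised."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.pad = kernel // 2
        fan_in = in_channels * kernel
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                      (out_channels, in_channels, kernel))
        self.params["b"] = np.zeros(out_channels)

    def n_params(self) -> int:
        return self.params["W"].size + self.params["b"].size

    def _im2col(self, xp: np.ndarray, length: int) -> np.ndarray:
        # xp: (batch, in_c, length + 2*pad) -> (batch, in_c * kernel, length)
        windows = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        # windows: (batch, in_c, length, kernel)
        return windows.transpose(0, 1, 3, 2).reshape(
            xp.shape[0], self.in_channels * self.kernel, length
        )

    def forward(self, x, training, rng):
        batch, _, length = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        self._cols = self._im2col(xp, length)  # (batch, in_c*k, L)
        self._length = length
        W2 = self.params["W"].reshape(self.out_channels, -1)
        out = np.einsum("of,bfl->bol", W2, self._cols, optimize=True)
        return out + self.params["b"][None, :, None]

    def backward(self, dout):
        # dout: (batch, out_c, L)
        W2 = self.params["W"].reshape(self.out_channels, -1)
        self.grads["b"] = dout.sum(axis=(0, 2))
        gW = np.einsum("bol,bfl->of", dout, self._cols, optimize=True)
        self.grads["W"] = gW.reshape(self.params["W"].shape)
        dcols = np.einsum("of,bol->bfl", W2, dout, optimize=True)
        # fold columns back (col2im)
        batch = dout.shape[0]
        L = self._length
        dxp = np.zeros((batch, self.in_channels, L + 2 * self.pad))
        dcols = dcols.reshape(batch, self.in_channels, self.kernel, L)
        for t in range(self.kernel):
            dxp[:, :, t : t + L] += dcols[:, :, t, :]
        return dxp[:, :, self.pad : self.pad + L]


class ReLU(Layer):
    def forward(self, x, training, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Sigmoid(Layer):
    def forward(self, x, training, rng):
        self._out = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._out

    def backward(self, dout):
        return dout * self._out * (1.0 - self._out)


class BatchNorm1D(Layer):
    """Per-channel batch normalization over (batch, length).

    Running statistics (momentum 0.9) are used in inference mode.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, training, rng):
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None]) / self._std[None, :, None]
        self._m = x.shape[0] * x.shape[2]
        self._training = training
        return (
            self.params["gamma"][None, :, None] * self._xhat
            + self.params["beta"][None, :, None]
        )

    def backward(self, dout):
        xhat, std, m = self._xhat, self._std, self._m
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 2))
        self.grads["beta"] = dout.sum(axis=(0, 2))
        g = self.params["gamma"][None, :, None]
        if not self._training:
            return dout * g / std[None, :, None]
        dxhat = dout * g
        term = (
            dxhat
            - dxhat.mean(axis=(0, 2), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2), keepdims=True)
        )
        return term / std[None, :, None]


class Dropout(Layer):
    """Inverted dropout: identity in inference mode."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.uniform(size=x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer with optional L2 weight penalty."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, l2: float = 0.0) -> None:
        super().__init__()
        self.l2 = l2
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / in_features), (in_features, out_features)
        )
        self.params["b"] = np.zeros(out_features)

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout + self.l2 * 2.0 * self.params["W"]
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T

    def l2_penalty(self) -> float:
        return self.l2 * float((self.params["W"] ** 2).sum())


class Network:
    """A plain layer stack with seeded forward/backward passes."""

    def __init__(self, layers: list[Layer], rng: np.random.Generator) -> None:
        self.layers = layers
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training, self.rng)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def l2_penalty(self) -> float:
        return sum(layer.l2_penalty() for layer in self.layers)

    def parameters(self, trainable_only: bool = False):
        """Yield (layer, name, array) triples in a fixed order."""
        for layer in self.layers:
            if trainable_only and not layer.trainable:
                continue
            for name in sorted(layer.params):
                yield layer, name, layer.params[name]

    def copy_weights(self) -> list[np.ndarray]:
        return [p.copy() for _, _, p in self.parameters()]


@dataclass
class Adam:
    """Adam optimizer over a :class:`Network`'s trainable parameters."""

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}
        self._t = 0

    def step(self, net: Network) -> None:
        self._t += 1
        for layer, name, p in net.parameters(trainable_only=True):
            g = layer.grads.get(name)
            if g is None:
                continue
            key = id(layer.params[name])
            m = self._m.setdefault(key, np.zeros_like(p))
            v = self._v.setdefault(key, np.zeros_like(p))
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            mhat = m / (1 - self.beta1**self._t)
            vhat = v / (1 - self.beta2**self._t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def mse_loss(pred: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient w.r.t. ``pred``."""
    diff = pred - y
    return float(np.mean(diff**2)), 2.0 * diff / diff.size


def bce_loss(prob: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Binary cross-entropy on sigmoid outputs and its gradient."""
    p = np.clip(prob, 1e-12, 1 - 1e-12)
    loss = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
    grad = (p - y) / (p * (1 - p)) / p.size
    return loss, grad
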