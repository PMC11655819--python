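"""Minimal numpy neural-network backend for EEG trial classification.

Implements exactly the pieces the compact EEG CNN needs — grouped 2-D
convolution, batch normalization, ELU, average pooling, dropout, a dense
sigmoid head — with hand-derived backward passes (verified against
numerical gradients in the test suite), an Adam optimizer with decoupled L2
weight decay, and two attribution methods over the same layer stack:
plain gradient x input and the DeepLIFT rescale rule.

Inputs are ``(batch, 1, channels, samples)`` arrays; the single output is a
logit passed through a sigmoid for binary classification.  All randomness
(initialization, dropout) flows from an explicit ``numpy`` Generator so
training is bit-reproducible given a seed.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ELU",
    "AvgPool2d",
    "Dropout",
    "Flatten",
    "Dense",
    "Sequential",
    "Adam",
    "bce_with_logits",
    "sigmoid",
    "gradient_input",
    "deeplift_rescale",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns ``(loss, dloss/dz)``."""
    z = z.reshape(-1)
    y = y.reshape(-1).astype(np.float64)
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    dz = (sigmoid(z) - y) / z.shape[0]
    return loss, dz.reshape(-1, 1)


class Layer:
    """Base layer: ``params``/``grads`` dicts plus forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def input_gradient(self, dout: np.ndarray) -> np.ndarray:
        """Gradient wrt the input only (no parameter-gradient accumulation)."""
        return self.backward(dout)


class Conv2d(Layer):
    """Grouped 2-D convolution (cross-correlation) with optional same-padding
    along the time (last) axis only."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: tuple[int, int],
        groups: int = 1,
        pad_same_time: bool = False,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channel counts must be divisible by groups")
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kh, self.kw = kernel
        self.groups = groups
        self.pad_same_time = pad_same_time
        rng = rng or np.random.default_rng(0)
        fan_in = (in_channels // groups) * self.kh * self.kw
        bound = 1.0 / np.sqrt(fan_in)
        self.params["W"] = rng.uniform(
            -bound, bound, (out_channels, in_channels // groups, self.kh, self.kw)
        )
        if bias:
            self.params["b"] = np.zeros(out_channels)
        self._cache = None

    def _pad(self, x: np.ndarray) -> tuple[np.ndarray, int]:
        if not self.pad_same_time or self.kw == 1:
            return x, 0
        left = (self.kw - 1) // 2
        right = self.kw - 1 - left
        return np.pad(x, ((0, 0), (0, 0), (0, 0), (left, right))), left

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        xp, left = self._pad(x)
        n, cin, hp, wp = xp.shape
        ho, wo = hp - self.kh + 1, wp - self.kw + 1
        win = sliding_window_view(xp, (self.kh, self.kw), axis=(2, 3))  # (n,cin,ho,wo,kh,kw)
        g, cg = self.groups, cin // self.groups
        og = self.out_channels // g
        w = self.params["W"]
        outs = []
        for gi in range(g):
            wv = win[:, gi * cg : (gi + 1) * cg]
            wg = w[gi * og : (gi + 1) * og]
            outs.append(np.einsum("ncijuv,ocuv->noij", wv, wg, optimize=True))
        out = np.concatenate(outs, axis=1)
        if "b" in self.params:
            out = out + self.params["b"][None, :, None, None]
        self._cache = (win, xp.shape, x.shape, left)
        return out

    def _input_grad(self, dout: np.ndarray, xp_shape, x_shape, left) -> np.ndarray:
        n, cin, hp, wp = xp_shape
        ho, wo = dout.shape[2], dout.shape[3]
        g, cg = self.groups, cin // self.groups
        og = self.out_channels // g
        w = self.params["W"]
        dxp = np.zeros(xp_shape)
        for gi in range(g):
            dg = dout[:, gi * og : (gi + 1) * og]
            wg = w[gi * og : (gi + 1) * og]
            for u in range(self.kh):
                for v in range(self.kw):
                    contrib = np.einsum("noij,oc->ncij", dg, wg[:, :, u, v], optimize=True)
                    dxp[:, gi * cg : (gi + 1) * cg, u : u + ho, v : v + wo] += contrib
        if left or dxp.shape != x_shape:
            w_in = x_shape[3]
            dxp = dxp[:, :, :, left : left + w_in]
        return dxp

    def backward(self, dout: np.ndarray) -> np.ndarray:
        win, xp_shape, x_shape, left = self._cache
        g = self.groups
        cg = xp_shape[1] // g
        og = self.out_channels // g
        dws = []
        for gi in range(g):
            wv = win[:, gi * cg : (gi + 1) * cg]
            dg = dout[:, gi * og : (gi + 1) * og]
            dws.append(np.einsum("ncijuv,noij->ocuv", wv, dg, optimize=True))
        self.grads["W"] = np.concatenate(dws, axis=0)
        if "b" in self.params:
            self.grads["b"] = dout.sum(axis=(0, 2, 3))
        return self._input_grad(dout, xp_shape, x_shape, left)

    def input_gradient(self, dout: np.ndarray) -> np.ndarray:
        _, xp_shape, x_shape, left = self._cache
        return self._input_grad(dout, xp_shape, x_shape, left)


class BatchNorm2d(Layer):
    """Per-feature-map batch normalization over (batch, height, width)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = (0, 2, 3)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        ivstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * ivstd[None, :, None, None]
        out = self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][None, :, None, None]
        self._cache = (x, xhat, mean, ivstd, training)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, xhat, mean, ivstd, training = self._cache
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = dout.sum(axis=(0, 2, 3))
        return self._dx(dout)

    def _dx(self, dout: np.ndarray) -> np.ndarray:
        x, xhat, mean, ivstd, training = self._cache
        gamma = self.params["gamma"][None, :, None, None]
        iv = ivstd[None, :, None, None]
        if not training:
            return dout * gamma * iv
        m = x.shape[0] * x.shape[2] * x.shape[3]
        dxhat = dout * gamma
        sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return iv * (dxhat - sum_dxhat / m - xhat * sum_dxhat_xhat / m)

    def input_gradient(self, dout: np.ndarray) -> np.ndarray:
        return self._dx(dout)


class ELU(Layer):
    def __init__(self, alpha: float = 1.0) -> None:
        super().__init__()
        self.alpha = alpha
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.where(x > 0, x, self.alpha * np.expm1(x))
        self._cache = (x, out)
        return out

    def derivative(self, x: np.ndarray) -> np.ndarray:
        return np.where(x > 0, 1.0, self.alpha * np.exp(x))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, _ = self._cache
        return dout * self.derivative(x)


class AvgPool2d(Layer):
    """Non-overlapping average pooling along the time axis, size ``(1, p)``.

    Trailing samples that do not fill a window are dropped.
    """

    def __init__(self, p: int) -> None:
        super().__init__()
        self.p = int(p)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        wo = w // self.p
        if wo < 1:
            raise ValueError(f"input width {w} shorter than pool size {self.p}")
        out = x[:, :, :, : wo * self.p].reshape(n, c, h, wo, self.p).mean(axis=4)
        self._cache = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._cache
        wo = dout.shape[3]
        dx = np.zeros((n, c, h, w))
        dx[:, :, :, : wo * self.p] = np.repeat(dout / self.p, self.p, axis=3)
        return dx


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.p = float(p)
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._shape = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / np.sqrt(n_in)
        self.params["W"] = rng.uniform(-bound, bound, (n_in, n_out))
        self.params["b"] = np.zeros(n_out)
        self._x = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T

    def input_gradient(self, dout: np.ndarray) -> np.ndarray:
        return dout @ self.params["W"].T


class Sequential:
    """A plain layer stack with a single-logit output."""

    def __init__(self, layers: Sequence[Layer]) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def predict_logit(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, training=False).reshape(-1)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.predict_logit(x))

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(layer, name) for layer in self.layers for name in layer.params]

    def state(self) -> list[np.ndarray]:
        out = [layer.params[name].copy() for layer, name in self.parameters()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm2d):
                out += [layer.running_mean.copy(), layer.running_var.copy()]
        return out


class Adam:
    """Adam with L2 weight decay applied to weight matrices (not biases/BN)."""

    def __init__(
        self,
        model: Sequential,
        lr: float = 0.05,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ) -> None:
        self.model = model
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {id(l) * 1000 + i: np.zeros_like(l.params[n])
                  for i, (l, n) in enumerate(model.parameters())}
        self.v = {k: np.zeros_like(val) for k, val in self.m.items()}

    def step(self) -> None:
        self.t += 1
        for i, (layer, name) in enumerate(self.model.parameters()):
            key = id(layer) * 1000 + i
            g = layer.grads.get(name)
            if g is None:
                continue
            if self.weight_decay and name == "W":
                g = g + self.weight_decay * layer.params[name]
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / (1 - self.b1**self.t)
            vhat = self.v[key] / (1 - self.b2**self.t)
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# attribution over a Sequential stack (evaluation mode)
# ---------------------------------------------------------------------------

def gradient_input(model: Sequential, x: np.ndarray) -> np.ndarray:
    """Gradient-times-input attribution of the output logit."""
    out = model.forward(x, training=False)
    dout = np.ones_like(out)
    for layer in reversed(model.layers):
        dout = layer.input_gradient(dout)
    return dout * x


def deeplift_rescale(
    model: Sequential,
    x: np.ndarray,
    baseline: np.ndarray | None = None,
    eps: float = 1e-7,
) -> np.ndarray:
    """DeepLIFT attributions of the output logit under the rescale rule.

    Contribution differences (activation minus baseline activation) are
    propagated through linear layers exactly like gradients; through each
    ELU the multiplier is the secant slope ``delta_out / delta_in``, falling
    back to the derivative where ``|delta_in| < eps``.  Satisfies the
    completeness identity: attributions sum to
    ``logit(x) - logit(baseline)``.
    """
    if baseline is None:
        baseline = np.zeros_like(x)
    # reference pass first so that layer caches afterwards belong to x
    acts_ref = [baseline]
    a = baseline
    for layer in model.layers:
        a = layer.forward(a, training=False)
        acts_ref.append(a)
    acts_x = [x]
    a = x
    for layer in model.layers:
        a = layer.forward(a, training=False)
        acts_x.append(a)

    m = np.ones_like(acts_x[-1])
    for k in reversed(range(len(model.layers))):
        layer = model.layers[k]
        if isinstance(layer, ELU):
            din = acts_x[k] - acts_ref[k]
            dout_act = acts_x[k + 1] - acts_ref[k + 1]
            slope = np.where(
                np.abs(din) > eps,
                dout_act / np.where(np.abs(din) > eps, din, 1.0),
                layer.derivative(acts_x[k]),
            )
            m = m * slope
        elif isinstance(layer, (Conv2d, BatchNorm2d, AvgPool2d, Dropout, Flatten, Dense)):
            m = layer.input_gradient(m)
        else:
            raise TypeError(
                f"DeepLIFT rescale is not defined for layer type {type(layer).__name__}"
            )
    return m * (x - baseline)
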