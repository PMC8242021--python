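"""A compact batched neural-network engine with native per-sample gradients.

Reverse-mode autodiff frameworks reduce weight gradients over the minibatch
axis inside the backward pass, which destroys exactly the quantity DP-SGD
needs: the gradient of each sample's loss on its own.  The layers here keep
the batch axis all the way through backpropagation — ``layer.grads[name]``
has shape ``(B, *param.shape)`` after a backward pass — so per-sample
gradients fall out of a single batched pass with no serial loop and no
per-layer special-casing.

Weight *storage* is allocated once per layer; everything downstream (the
replica views of :mod:`privgrad.engine`) aliases these arrays.

The layer set is deliberately small (dense, 2-D convolution, pooling,
nearest-neighbour upsampling, ReLU/sigmoid, batch/group normalisation) but
sufficient for the small classification CNNs and encoder–decoder
segmentation nets used throughout the package.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Linear",
    "Conv2d",
    "AvgPool2d",
    "Upsample2d",
    "ReLU",
    "Sigmoid",
    "Flatten",
    "BatchNorm2d",
    "GroupNorm",
    "Sequential",
    "softmax_cross_entropy",
    "bce_with_logits",
    "SGD",
    "Adam",
]

_BN_EPS = 1e-5


class Layer:
    """Base layer: parameter dict + per-sample gradient dict.

    ``params[name]`` is the single shared storage for that parameter.
    After ``backward``, ``grads[name]`` holds per-sample gradients of shape
    ``(B,) + params[name].shape``; ``agg_grads[name]`` is the slot the
    DP engine (or a plain mean-reduction) writes for the optimiser.
    """

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.agg_grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.forward(x, train=train)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = math.sqrt(2.0 / in_features)
        self.params["weight"] = rng.normal(0.0, bound, (out_features, in_features))
        self.params["bias"] = np.zeros(out_features)

    def forward(self, x, train=True):
        self._x = x
        return x @ self.params["weight"].T + self.params["bias"]

    def backward(self, gout):
        self.grads["weight"] = np.einsum("bo,bi->boi", gout, self._x)
        self.grads["bias"] = gout
        return gout @ self.params["weight"]


class Conv2d(Layer):
    """2-D convolution (cross-correlation) with 'same'-style integer padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        k = kernel_size
        fan_in = in_channels * k * k
        self.params["weight"] = rng.normal(
            0.0, math.sqrt(2.0 / fan_in), (out_channels, in_channels, k, k)
        )
        self.params["bias"] = np.zeros(out_channels)
        self.kernel_size, self.stride, self.padding = k, stride, padding

    def forward(self, x, train=True):
        k, s, p = self.kernel_size, self.stride, self.padding
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._xp = x
        # windows: (B, C, Ho, Wo, k, k)
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        self._win = win
        y = np.einsum("bchwij,ocij->bohw", win, self.params["weight"])
        return y + self.params["bias"][None, :, None, None]

    def backward(self, gout):
        k, s, p = self.kernel_size, self.stride, self.padding
        self.grads["weight"] = np.einsum("bohw,bchwij->bocij", gout, self._win)
        self.grads["bias"] = gout.sum(axis=(2, 3))
        B, C, Hp, Wp = self._xp.shape
        Ho, Wo = gout.shape[2], gout.shape[3]
        gxp = np.zeros_like(self._xp)
        gcols = np.einsum("bohw,ocij->bchwij", gout, self.params["weight"])
        for i in range(k):
            for j in range(k):
                gxp[:, :, i:i + Ho * s:s, j:j + Wo * s:s] += gcols[:, :, :, :, i, j]
        if p:
            gxp = gxp[:, :, p:-p, p:-p]
        return gxp


class AvgPool2d(Layer):
    """Non-overlapping average pooling; spatial dims must divide the window."""

    def __init__(self, kernel_size: int = 2):
        super().__init__()
        self.k = kernel_size

    def forward(self, x, train=True):
        B, C, H, W = x.shape
        k = self.k
        if H % k or W % k:
            raise ValueError(f"spatial dims {(H, W)} not divisible by pool size {k}")
        self._in_shape = x.shape
        return x.reshape(B, C, H // k, k, W // k, k).mean(axis=(3, 5))

    def backward(self, gout):
        k = self.k
        g = np.repeat(np.repeat(gout, k, axis=2), k, axis=3)
        return g / (k * k)


class Upsample2d(Layer):
    """Nearest-neighbour upsampling by an integer factor."""

    def __init__(self, scale: int = 2):
        super().__init__()
        self.scale = scale

    def forward(self, x, train=True):
        s = self.scale
        return np.repeat(np.repeat(x, s, axis=2), s, axis=3)

    def backward(self, gout):
        s = self.scale
        B, C, H, W = gout.shape
        return gout.reshape(B, C, H // s, s, W // s, s).sum(axis=(3, 5))


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout):
        return gout * self._mask


class Sigmoid(Layer):
    def forward(self, x, train=True):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, gout):
        return gout * self._y * (1.0 - self._y)


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout):
        return gout.reshape(self._shape)


def _norm_backward(gout, xhat, inv_std, gamma, axes):
    """Shared backward for normalisation over per-sample axis set ``axes``.

    With population statistics, dL/dx =
    inv_std * (t - mean(t) - xhat * mean(t * xhat)), t = gout * gamma,
    means taken over the normalisation set of each sample.
    """
    t = gout * gamma
    m1 = t.mean(axis=axes, keepdims=True)
    m2 = (t * xhat).mean(axis=axes, keepdims=True)
    return inv_std * (t - m1 - xhat * m2)


class BatchNorm2d(Layer):
    """Batch normalisation over (B, C, H, W) with optional running statistics.

    With ``track_running_stats=True`` (the default, mirroring common
    pretrained architectures) the layer accumulates exponential moving
    averages of the minibatch mean/variance — state shared across samples,
    which is exactly what makes it incompatible with per-sample gradient
    semantics.  DP model surgery flips the layer into *per-sample
    statistics* mode: each sample is normalised by its own per-channel
    spatial moments in training and evaluation alike (for a single sample
    this coincides with instance normalisation), no cross-sample state is
    read or written, and the learnable affine parameters are untouched.
    """

    def __init__(self, num_features: int, momentum: float = 0.1,
                 track_running_stats: bool = True):
        super().__init__()
        self.num_features = num_features
        self.momentum = momentum
        self.track_running_stats = track_running_stats
        self.per_sample_stats = not track_running_stats
        self.params["gamma"] = np.ones(num_features)
        self.params["beta"] = np.zeros(num_features)
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def forward(self, x, train=True):
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        if self.per_sample_stats:
            axes = (2, 3)  # each sample's own spatial moments
            mean = x.mean(axis=axes, keepdims=True)
            var = x.var(axis=axes, keepdims=True)
        elif train:
            axes = (0, 2, 3)
            mean = x.mean(axis=axes, keepdims=True)
            var = x.var(axis=axes, keepdims=True)
            if self.track_running_stats:
                m = self.momentum
                self.running_mean = (1 - m) * self.running_mean + m * mean.squeeze()
                self.running_var = (1 - m) * self.running_var + m * var.squeeze()
        else:
            mean = self.running_mean[None, :, None, None]
            var = self.running_var[None, :, None, None]
            axes = None
        self._axes = axes
        self._inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        self._xhat = (x - mean) * self._inv_std
        return g * self._xhat + b

    def backward(self, gout):
        self.grads["gamma"] = (gout * self._xhat).sum(axis=(2, 3))
        self.grads["beta"] = gout.sum(axis=(2, 3))
        g = self.params["gamma"][None, :, None, None]
        if self._axes is None:  # eval with frozen running stats
            return gout * g * self._inv_std
        return _norm_backward(gout, self._xhat, self._inv_std, g, self._axes)


class GroupNorm(Layer):
    """Group normalisation: per-sample statistics over channel groups.

    Inherently DP-compatible — every statistic is computed within one
    sample.  Offered by model surgery as the opt-in substitution strategy
    for batch normalisation.
    """

    def __init__(self, num_groups: int, num_features: int):
        super().__init__()
        if num_features % num_groups:
            raise ValueError("num_features must be divisible by num_groups")
        self.num_groups = num_groups
        self.num_features = num_features
        self.params["gamma"] = np.ones(num_features)
        self.params["beta"] = np.zeros(num_features)

    def forward(self, x, train=True):
        B, C, H, W = x.shape
        G = self.num_groups
        xg = x.reshape(B, G, C // G, H, W)
        mean = xg.mean(axis=(2, 3, 4), keepdims=True)
        var = xg.var(axis=(2, 3, 4), keepdims=True)
        self._inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        self._xhat_g = (xg - mean) * self._inv_std
        self._shape = x.shape
        xhat = self._xhat_g.reshape(B, C, H, W)
        self._xhat = xhat
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        return g * xhat + b

    def backward(self, gout):
        B, C, H, W = self._shape
        G = self.num_groups
        self.grads["gamma"] = (gout * self._xhat).sum(axis=(2, 3))
        self.grads["beta"] = gout.sum(axis=(2, 3))
        gamma_g = self.params["gamma"].reshape(1, G, C // G, 1, 1)
        gout_g = gout.reshape(B, G, C // G, H, W)
        gx = _norm_backward(gout_g, self._xhat_g, self._inv_std, gamma_g, (2, 3, 4))
        return gx.reshape(B, C, H, W)


class Sequential:
    """An ordered container of layers with shared-storage parameter access."""

    def __init__(self, *layers: Layer):
        self.layers: list[Layer] = list(layers)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    __call__ = forward

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout

    def named_parameters(self) -> Iterator[tuple[str, np.ndarray]]:
        for i, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                yield f"{i}.{type(layer).__name__}.{name}", p

    def named_layers(self) -> Iterator[tuple[str, Layer]]:
        for i, layer in enumerate(self.layers):
            yield f"{i}.{type(layer).__name__}", layer

    @property
    def num_params(self) -> int:
        return sum(p.size for _, p in self.named_parameters())

    def per_sample_flat_grads(self) -> np.ndarray:
        """Stack every layer's per-sample gradients into a (B, P) matrix."""
        chunks = []
        B = None
        for layer in self.layers:
            for name in layer.params:
                g = layer.grads[name]
                B = g.shape[0]
                chunks.append(g.reshape(B, -1))
        if not chunks:
            return np.zeros((0, 0))
        return np.concatenate(chunks, axis=1)

    def set_flat_grad(self, flat: np.ndarray) -> None:
        """Scatter a flat (P,) gradient into each layer's optimiser slot."""
        if flat.ndim != 1 or flat.size != self.num_params:
            raise ValueError(
                f"flat gradient has {flat.size} entries, model has {self.num_params}"
            )
        ofs = 0
        for layer in self.layers:
            for name, p in layer.params.items():
                layer.agg_grads[name] = flat[ofs:ofs + p.size].reshape(p.shape)
                ofs += p.size

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.grads.clear()
            layer.agg_grads.clear()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.copy() for name, p in self.named_parameters()}
        for lname, layer in self.named_layers():
            if isinstance(layer, BatchNorm2d):
                state[f"{lname}.running_mean"] = layer.running_mean.copy()
                state[f"{lname}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p[...] = state[name]
        for lname, layer in self.named_layers():
            if isinstance(layer, BatchNorm2d):
                layer.running_mean = state[f"{lname}.running_mean"].copy()
                layer.running_var = state[f"{lname}.running_var"].copy()


# ---------------------------------------------------------------------------
# losses — per-sample by construction (no batch reduction)
# ---------------------------------------------------------------------------

def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray,
    class_weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample weighted cross-entropy and its gradient w.r.t. logits.

    Returns ``(losses, grad)`` with ``losses`` of shape (B,) and ``grad``
    of the logits' shape; no mean over the batch is taken, so downstream
    per-sample gradients remain attributable.
    """
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    B = logits.shape[0]
    w = np.ones(B) if class_weights is None else class_weights[labels]
    losses = -w * logp[np.arange(B), labels]
    p = np.exp(logp)
    grad = p.copy()
    grad[np.arange(B), labels] -= 1.0
    grad *= w[:, None]
    return losses, grad


def bce_with_logits(
    logits: np.ndarray, targets: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample mean binary cross-entropy over all non-batch dims.

    ``logits`` and ``targets`` share a shape with leading batch axis;
    each sample's loss is the mean pixelwise BCE, keeping losses O(1)
    regardless of image size.
    """
    x = np.clip(logits, -60, 60)
    losses_elem = np.logaddexp(0.0, x) - targets * x
    B = logits.shape[0]
    npix = logits[0].size
    losses = losses_elem.reshape(B, -1).mean(axis=1)
    sig = 1.0 / (1.0 + np.exp(-x))
    grad = (sig - targets) / npix
    return losses, grad


# ---------------------------------------------------------------------------
# optimisers — consume the aggregated gradient slots
# ---------------------------------------------------------------------------

class SGD:
    def __init__(self, model: Sequential, lr: float, momentum: float = 0.0):
        self.model = model
        self.lr = lr
        self.momentum = momentum
        self._vel: dict[int, dict[str, np.ndarray]] = {}

    def step(self) -> None:
        for i, layer in enumerate(self.model.layers):
            for name, p in layer.params.items():
                g = layer.agg_grads[name]
                if self.momentum:
                    v = self._vel.setdefault(i, {}).setdefault(name, np.zeros_like(p))
                    v *= self.momentum
                    v += g
                    g = v
                p -= self.lr * g


class Adam:
    def __init__(self, model: Sequential, lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self._t = 0
        self._m: dict[int, dict[str, np.ndarray]] = {}
        self._v: dict[int, dict[str, np.ndarray]] = {}

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.b1, self.b2
        for i, layer in enumerate(self.model.layers):
            for name, p in layer.params.items():
                g = layer.agg_grads[name]
                m = self._m.setdefault(i, {}).setdefault(name, np.zeros_like(p))
                v = self._v.setdefault(i, {}).setdefault(name, np.zeros_like(p))
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                mhat = m / (1 - b1**self._t)
                vhat = v / (1 - b2**self._t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
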