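"""Minimal CNN engine with explicit backpropagation.

Implements exactly the pieces the desk-scale backbone needs: 2-D
convolution (im2col), ReLU, 2x2 max pooling, global average pooling, a
dense softmax head, weighted cross-entropy, and an Adam optimizer.
Activations and gradients of any layer can be captured, which is what
class-activation mapping requires.

Array convention: images are (N, C, H, W) float32.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Conv2D",
    "ReLU",
    "MaxPool2D",
    "GlobalAvgPool",
    "Dense",
    "Sequential",
    "Adam",
    "softmax",
    "kaiming_normal",
    "tiny_cnn",
]


def kaiming_normal(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    """He fan-in normal initialisation, suited to ReLU networks."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _im2col(x: np.ndarray, k: int, pad: int):
    """(N,C,H,W) -> (N, C*k*k, Hp*Wp) patch matrix, stride 1."""
    n, c, h, w = x.shape
    hp, wp = h + 2 * pad - k + 1, w + 2 * pad - k + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, k, k, hp, wp),
        strides=(s[0], s[1], s[2], s[3], s[2], s[3]),
        writeable=False,
    )
    return windows.reshape(n, c * k * k, hp * wp), (hp, wp)


def _col2im(cols: np.ndarray, x_shape: tuple, k: int, pad: int) -> np.ndarray:
    """Adjoint of _im2col: scatter patch-matrix gradients back to the image."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad - k + 1, w + 2 * pad - k + 1
    cols = cols.reshape(n, c, k, k, hp, wp)
    out = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for di in range(k):
        for dj in range(k):
            out[:, :, di : di + hp, dj : dj + wp] += cols[:, :, di, dj]
    if pad:
        out = out[:, :, pad:-pad, pad:-pad]
    return out


class Layer:
    """Base layer: forward caches what backward needs; params/grads lists."""

    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 (or kxk) same-padding convolution, stride 1."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        fan_in = in_ch * k * k
        self.w = kaiming_normal(rng, (out_ch, in_ch, k, k), fan_in)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.k, self.pad = k, k // 2
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        cols, (hp, wp) = _im2col(x, self.k, self.pad)
        self._cols = cols
        wmat = self.w.reshape(self.w.shape[0], -1)  # (out, C*k*k)
        out = np.einsum("of,nfp->nop", wmat, cols) + self.b[None, :, None]
        return out.reshape(x.shape[0], -1, hp, wp)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, o, hp, wp = dout.shape
        dflat = dout.reshape(n, o, hp * wp)
        wmat = self.w.reshape(o, -1)
        self.grads[0][...] = np.einsum("nop,nfp->of", dflat, self._cols).reshape(self.w.shape)
        self.grads[1][...] = dflat.sum(axis=(0, 2))
        dcols = np.einsum("of,nop->nfp", wmat, dflat)
        return _col2im(dcols, self._x_shape, self.k, self.pad)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2; input H, W must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        self._shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        # split gradient equally among tied maxima so the adjoint stays exact
        counts = self._mask.sum(axis=(3, 5), keepdims=True)
        dx = self._mask * (dout[:, :, :, None, :, None] / counts)
        return dx.reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        self.w = kaiming_normal(rng, (n_in, n_out), n_in)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.w.T


class Sequential:
    """Plain layer stack with full-network and from-layer forward passes."""

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def forward_from(self, layer_idx: int, a: np.ndarray) -> np.ndarray:
        """Forward pass starting *after* layer ``layer_idx`` given its output."""
        x = a
        for layer in self.layers[layer_idx + 1 :]:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray, down_to: int = 0) -> np.ndarray:
        """Backpropagate; returns the gradient w.r.t. the output of layer
        ``down_to - 1`` (i.e. the input of layer ``down_to``)."""
        for layer in reversed(self.layers[down_to:]):
            dout = layer.backward(dout)
        return dout

    @property
    def params(self) -> list:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list:
        return [g for layer in self.layers for g in layer.grads]

    def parameterized_layers(self) -> list:
        return [l for l in self.layers if l.params]

    def logits(self, x: np.ndarray) -> np.ndarray:
        return self.forward(np.asarray(x, dtype=np.float32))

    def predict_proba_batch(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.logits(x), axis=1)

    def activation_and_gradient(
        self, x: np.ndarray, class_idx: int, layer_idx: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """Output of layer ``layer_idx`` and d(logit_c)/d(that output).

        Used by Grad-CAM: the class score is the pre-softmax logit of
        ``class_idx`` summed over the batch.
        """
        out = self.forward(np.asarray(x, dtype=np.float32))
        dout = np.zeros_like(out)
        dout[:, class_idx] = 1.0
        for layer in reversed(self.layers[layer_idx + 1 :]):
            dout = layer.backward(dout)
        # activations were cached during forward; recompute cheaply
        a = np.asarray(x, dtype=np.float32)
        for layer in self.layers[: layer_idx + 1]:
            a = layer.forward(a)
        return a, dout

    def state_dict(self) -> dict:
        return {f"p{i}": p for i, p in enumerate(self.params)}

    def load_state_dict(self, state: dict) -> None:
        for i, p in enumerate(self.params):
            p[...] = state[f"p{i}"]


class Adam:
    """Adam update  theta <- theta - lr * m_hat / (sqrt(v_hat) + eps)."""

    def __init__(self, params: Sequence[np.ndarray], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0
        self.frozen: set[int] = set()

    def freeze(self, params: Sequence[np.ndarray]) -> None:
        ids = {id(p) for p in params}
        self.frozen |= {i for i, p in enumerate(self.params) if id(p) in ids}

    def step(self, grads: Sequence[np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(zip(self.params, grads)):
            if i in self.frozen:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


def tiny_cnn(n_classes: int, in_ch: int = 3, width: int = 8,
             rng: Optional[np.random.Generator] = None) -> Sequential:
    """Desk-scale backbone: three conv blocks, GAP, softmax head.

    Stands in for a large pretrained backbone in tests and examples; the
    training recipe and the routing framework are backbone-agnostic.
    """
    rng = rng or np.random.default_rng()
    return Sequential([
        Conv2D(in_ch, width, rng=rng), ReLU(), MaxPool2D(),
        Conv2D(width, 2 * width, rng=rng), ReLU(), MaxPool2D(),
        Conv2D(2 * width, 4 * width, rng=rng), ReLU(),
        GlobalAvgPool(),
        Dense(4 * width, n_classes, rng=rng),
    ])
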