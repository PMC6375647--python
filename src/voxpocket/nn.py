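"""Minimal NumPy implementation of 3D convolutional networks.

Provides exactly the layer vocabulary the pocket classifier needs — valid 3D
convolution, leaky ReLU, dropout, max pooling, dense layers, softmax with
cross-entropy, and the Adam optimizer — with reverse-mode gradients
throughout.  Convolutions use a shift-and-matmul scheme (one GEMM per kernel
offset), which keeps memory flat and routes the arithmetic through BLAS.

Gradients are also exposed with respect to intermediate convolutional
activations, which is what gradient-weighted class-activation mapping needs.

Tensor layout is channels-last: (batch, depth, height, width, channels).
"""

from __future__ import annotations

from itertools import product

import numpy as np


class Layer:
    """Base layer: stateless unless it owns parameters."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, train=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Conv3D(Layer):
    """Valid (no padding), stride-1 3D convolution."""

    def __init__(self, in_channels: int, filters: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.kernel = kernel
        fan_in = kernel**3 * in_channels
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (kernel, kernel, kernel, in_channels, filters))
        b = np.zeros(filters)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x, train=False, rng=None):
        w, b = self.params
        k = self.kernel
        B, D, H, W, _ = x.shape
        Do, Ho, Wo = D - k + 1, H - k + 1, W - k + 1
        if min(Do, Ho, Wo) <= 0:
            raise ValueError(f"input spatial size too small for kernel {k}")
        out = np.broadcast_to(b, (B, Do, Ho, Wo, w.shape[-1])).copy()
        for di, dj, dk in product(range(k), repeat=3):
            out += x[:, di:di + Do, dj:dj + Ho, dk:dk + Wo, :] @ w[di, dj, dk]
        self._x = x
        return out

    def backward(self, dout):
        w, _ = self.params
        k = self.kernel
        x = self._x
        B, Do, Ho, Wo, F = dout.shape
        dw, db = self.grads
        db[...] = dout.sum(axis=(0, 1, 2, 3))
        dx = np.zeros_like(x)
        for di, dj, dk in product(range(k), repeat=3):
            x_slice = x[:, di:di + Do, dj:dj + Ho, dk:dk + Wo, :]
            dw[di, dj, dk] = np.tensordot(x_slice, dout, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
            dx[:, di:di + Do, dj:dj + Ho, dk:dk + Wo, :] += dout @ w[di, dj, dk].T
        return dx


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.1):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, train=False, rng=None):
        self._mask = x >= 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.alpha * dout)


class Dropout(Layer):
    """Inverted dropout; identity in inference mode."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class MaxPool3D(Layer):
    """Non-overlapping max pooling; trailing rows/planes beyond a full window are cropped."""

    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x, train=False, rng=None):
        s = self.size
        B, D, H, W, C = x.shape
        d, h, w = D // s, H // s, W // s
        x = x[:, :d * s, :h * s, :w * s, :]
        self._in_shape = x.shape
        win = x.reshape(B, d, s, h, s, w, s, C)
        out = win.max(axis=(2, 4, 6))
        # gradient mask; ties share the gradient equally
        eq = (win == out[:, :, None, :, None, :, None, :])
        self._mask = eq / eq.sum(axis=(2, 4, 6), keepdims=True)
        self._orig_shape = (B, D, H, W, C)
        return out

    def backward(self, dout):
        B, D, H, W, C = self._orig_shape
        s = self.size
        d, h, w = D // s, H // s, W // s
        dwin = self._mask * dout[:, :, None, :, None, :, None, :]
        dx = np.zeros((B, D, H, W, C))
        dx[:, :d * s, :h * s, :w * s, :] = dwin.reshape(B, d * s, h * s, w * s, C)
        return dx


class GlobalAvgPool(Layer):
    """Average over all spatial positions; used by the plain-CAM head variant."""

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.mean(axis=(1, 2, 3))

    def backward(self, dout):
        B, D, H, W, C = self._shape
        return np.broadcast_to(dout[:, None, None, None, :] / (D * H * W), self._shape).copy()


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), (in_features, out_features))
        b = np.zeros(out_features)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, dout):
        w, _ = self.params
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ w.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean categorical cross-entropy for integer labels."""
    p = np.clip(probs[np.arange(len(labels)), labels], 1e-12, None)
    return float(-np.log(p).mean())


class Network:
    """A feed-forward stack ending in logits; softmax applied on top."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x, train=False, rng=None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def predict_proba(self, x) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    def train_step(self, x, labels, rng) -> float:
        """One forward/backward pass; fills gradients and returns the loss."""
        logits = self.forward(x, train=True, rng=rng)
        probs = softmax(logits)
        loss = cross_entropy(probs, labels)
        dlogits = probs.copy()
        dlogits[np.arange(len(labels)), labels] -= 1.0
        dlogits /= len(labels)
        dout = dlogits
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return loss

    def activation_gradient(self, x, class_index: int, layer_index: int,
                            contrast: bool = False):
        """Activation at ``layers[layer_index]``'s output and its class gradient.

        Runs inference-mode forward, then backpropagates the unnormalized class
        logit from the head down to the requested layer output.  With
        ``contrast=True`` the target is logit_c - mean of the other logits,
        which removes the shared logit component that softmax never resolves.
        """
        acts = [x]
        for layer in self.layers:
            acts.append(layer.forward(acts[-1], train=False))
        logits = acts[-1]
        k = logits.shape[-1]
        if not 0 <= class_index < k:
            raise IndexError(f"class index {class_index} out of range")
        dout = np.zeros_like(logits)
        if contrast and k > 1:
            dout[...] = -1.0 / (k - 1)
        dout[:, class_index] = 1.0
        for layer in reversed(self.layers[layer_index + 1:]):
            dout = layer.backward(dout)
        return acts[layer_index + 1], dout


class Adam:
    """Adam with optional time-based learning-rate decay (lr / (1 + decay * t))."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-5, decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.decay = lr, decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr = self.lr / (1.0 + self.decay * (self.t - 1))
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
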