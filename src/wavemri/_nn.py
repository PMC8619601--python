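"""Minimal numpy neural-network layers with backpropagation.

Internal computational core for the block-wise CNN: im2col convolution,
spatial batch normalization, ReLU/tanh, 2x2 max pooling, inverted dropout,
dense layers and Adam. Tensors are NCHW float32 inside the network; the
public model module converts from the NHWC image layout at the boundary.

Everything is driven by explicit ``numpy.random.Generator`` instances, so a
training run is bit-reproducible from its seed on a fixed numpy version.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer: forward caches whatever backward needs."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params_grads(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []


def _same_pad(size: int, kernel: int, stride: int) -> tuple[int, int, int]:
    """(out_size, pad_before, pad_after) for 'same' padding."""
    out = -(-size // stride)  # ceil
    total = max((out - 1) * stride + kernel - size, 0)
    return out, total // 2, total - total // 2


class Conv2D(Layer):
    """2D convolution (cross-correlation), 'same' padding, He-normal init."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: tuple[int, int],
        stride: int,
        rng: np.random.Generator,
    ):
        kh, kw = kernel
        fan_in = in_channels * kh * kw
        self.W = (rng.standard_normal((out_channels, in_channels, kh, kw))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.stride = stride
        self.kernel = (kh, kw)

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        oh, _, _ = _same_pad(h, self.kernel[0], self.stride)
        ow, _, _ = _same_pad(w, self.kernel[1], self.stride)
        return oh, ow

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        kh, kw = self.kernel
        s = self.stride
        oh, pt, pb = _same_pad(h, kh, s)
        ow, pl, pr = _same_pad(w, kw, s)
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        # (N, C, oh, ow, kh, kw) strided view over the padded input
        win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * kh * kw)
        w_mat = self.W.reshape(self.W.shape[0], -1)
        y = cols @ w_mat.T + self.b
        self._cache = (cols, x.shape, (pt, pb, pl, pr), (oh, ow))
        return np.ascontiguousarray(
            y.reshape(n, oh, ow, -1).transpose(0, 3, 1, 2)
        )

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape, (pt, pb, pl, pr), (oh, ow) = self._cache
        n, c, h, w = x_shape
        kh, kw = self.kernel
        s = self.stride
        c_out = dout.shape[1]
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * oh * ow, c_out)
        self.dW[...] = (dmat.T @ cols).reshape(self.W.shape)
        self.db[...] = dmat.sum(axis=0)
        dcols = (dmat @ self.W.reshape(c_out, -1)).reshape(n, oh, ow, c, kh, kw)
        dcols = dcols.transpose(0, 3, 4, 5, 1, 2)  # (N, C, kh, kw, oh, ow)
        dxp = np.zeros((n, c, h + pt + pb, w + pl + pr), dtype=dout.dtype)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i : i + s * oh : s, j : j + s * ow : s] += dcols[:, :, i, j]
        return dxp[:, :, pt : pt + h, pl : pl + w]

    def params_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


class BatchNorm2D(Layer):
    """Per-channel mini-batch standardization with learned scale/offset.

    Standardizes by the mini-batch mean and variance (stability factor eps
    in the denominator), then applies gamma * xhat + beta. Running averages
    (momentum 0.9) are used at inference time.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.9):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    @property
    def n_params(self) -> int:
        return self.gamma.size + self.beta.size

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mu
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu.reshape(1, -1, 1, 1)) * inv_std.reshape(1, -1, 1, 1)
        self._cache = (xhat, inv_std, train)
        return (g * xhat + b).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, train = self._cache
        self.dgamma[...] = (dout * xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = dout.sum(axis=(0, 2, 3))
        g = self.gamma.reshape(1, -1, 1, 1)
        if not train:
            return dout * g * inv_std.reshape(1, -1, 1, 1)
        n, c, h, w = dout.shape
        m = n * h * w
        dxhat = dout * g
        sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (inv_std.reshape(1, -1, 1, 1) / m) * (
            m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat
        )
        return dx.astype(np.float32)

    def params_grads(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0)


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; spatial dims must be even.

    Ties route the gradient to the first maximal element of the window.
    """

    def forward(self, x, train):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"max-pool requires even spatial dims, got {h}x{w}")
        win = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        win = win.reshape(n, c, h // 2, w // 2, 4)
        self._argmax = win.argmax(axis=-1)
        self._in_shape = x.shape
        return win.max(axis=-1)

    def backward(self, dout):
        n, c, h, w = self._in_shape
        onehot = np.eye(4, dtype=dout.dtype)[self._argmax]  # (n,c,h/2,w/2,4)
        grad = onehot * dout[..., None]
        grad = grad.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(grad.reshape(n, c, h, w))


class Dropout(Layer):
    """Inverted dropout: active only in training, identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer, Glorot-uniform init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T

    def params_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Tanh(Layer):
    def forward(self, x, train):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout):
        return dout * (1.0 - self._y**2)


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy from logits; returns (loss, dloss/dlogits).

    Computed as ``y*softplus(-z) + (1-y)*softplus(z)`` which never overflows;
    the gradient is the classic ``(sigmoid(z) - y) / n``.
    """
    z = logits.astype(np.float64)
    softplus = np.logaddexp(0.0, z)
    loss = float(np.mean(y * (softplus - z) + (1.0 - y) * softplus))
    grad = ((sigmoid(z) - y) / z.size).astype(np.float32)
    return loss, grad


class Adam:
    """Adam optimizer over a list of (param, grad) pairs."""

    def __init__(self, params_grads, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.pg = params_grads
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params_grads]
        self.v = [np.zeros_like(p) for p, _ in params_grads]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for (p, g), m, v in zip(self.pg, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
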