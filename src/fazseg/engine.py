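"""Minimal NumPy neural-network engine used by the segmentation models.

Layers operate on NHWC float32 tensors and implement explicit forward /
backward passes.  Each layer instance owns its parameters (``params``),
accumulated gradients (``grads``) and any cache needed for the backward
pass, so a layer object must appear exactly once in a network graph.

Conventions
-----------
* Convolutions use "same" padding; weights are stored as (kh, kw, cin, cout).
* Batch normalization keeps Keras-style state: two trainable parameters
  (gamma, beta) and two non-trainable moving statistics per channel.  All
  four enter the parameter count; only the first two are updated by the
  optimizer.
* He-normal initialization (std = sqrt(2 / fan_in)) for conv and dense
  weights, zeros for biases.
"""

from __future__ import annotations

import numpy as np


__all__ = [
    "Layer", "Conv2D", "ConvTranspose2D", "BatchNorm", "ReLU", "Sigmoid",
    "MaxPool2", "UpSample2", "Dropout", "ChannelAttention", "Adam",
    "he_normal",
]


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Layer:
    """Base class; parameter-free layers inherit the empty defaults."""

    params: list
    grads: list
    # names parallel to params, used for checkpointing
    param_names: list

    def __init__(self):
        self.params, self.grads, self.param_names = [], [], []

    def forward(self, x, training=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))

    def zero_grad(self):
        for g in self.grads:
            g[...] = 0.0


class Conv2D(Layer):
    """k x k convolution, stride 1, same padding, with bias.

    The 3x3 path avoids im2col: for each kernel row the (row-contiguous)
    padded input block is multiplied against the three stacked kernel
    taps in a single GEMM and the result is added at the shifted column
    positions.  This keeps memory traffic near the tensor size instead
    of k^2 times it.
    """

    def __init__(self, cin, cout, k=3, rng=None, use_bias=True):
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        rng = rng or np.random.default_rng(0)
        self.W = he_normal(rng, (k, k, cin, cout), fan_in=k * k * cin)
        self.params = [self.W]
        self.param_names = ["W"]
        self.use_bias = use_bias
        if use_bias:
            self.b = np.zeros(cout, dtype=np.float32)
            self.params.append(self.b)
            self.param_names.append("b")
        self.grads = [np.zeros_like(p) for p in self.params]
        self._x = None

    def forward(self, x, training=False):
        self._x = x
        n, h, w, cin = x.shape
        cout, k = self.cout, self.k
        if k == 1:
            y = x.reshape(-1, cin) @ self.W.reshape(cin, cout)
            if self.use_bias:
                y += self.b
            return y.reshape(n, h, w, cout)
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._xp = xp
        y = np.zeros((n, h, w, cout), dtype=np.float32)
        for i in range(n):
            xi = xp[i]
            for di in range(k):
                block = xi[di:di + h].reshape(-1, cin)   # contiguous rows
                for dj in range(k):
                    z = (block @ self.W[di, dj]).reshape(h, w + 2 * p, cout)
                    y[i] += z[:, dj:dj + w, :]
        if self.use_bias:
            y += self.b
        return y

    def backward(self, dy):
        x = self._x
        n, h, w, cin = x.shape
        cout, k = self.cout, self.k
        dyf = dy.reshape(-1, cout)
        if self.use_bias:
            self.grads[-1] += dyf.sum(axis=0)
        if k == 1:
            self.grads[0] += (x.reshape(-1, cin).T @ dyf
                              ).reshape(self.W.shape)
            return (dyf @ self.W.reshape(cin, cout).T).reshape(x.shape)
        p = k // 2
        xp = self._xp
        dyp = np.pad(dy, ((0, 0), (p, p), (p, p), (0, 0)))
        dx = np.zeros_like(x)
        dW = np.zeros_like(self.W)
        dys = np.zeros((h, w + 2 * p, k, cout), dtype=np.float32)
        for i in range(n):
            dyi = dyp[i]
            xi = xp[i]
            for di in range(k):
                # dx[a] += dy[a + p - di] @ W[di]^T, via contiguous row blocks
                block = dyi[k - 1 - di:k - 1 - di + h].reshape(-1, cout)
                for dj in range(k):
                    z = (block @ self.W[di, dj].T).reshape(h, w + 2 * p, cin)
                    dx[i] += z[:, k - 1 - dj:k - 1 - dj + w, :]
            # weight gradient: stack column-shifted copies of dy once,
            # then one GEMM per kernel row
            dys[...] = 0.0
            for dj in range(k):
                dys[:, dj:dj + w, dj, :] = dy[i]
            dysf = dys.reshape(-1, k * cout)
            for di in range(k):
                g = xi[di:di + h].reshape(-1, cin).T @ dysf
                dW[di] += g.reshape(cin, k, cout).transpose(1, 0, 2)
        self.grads[0] += dW
        self._xp = None
        return dx


class ConvTranspose2D(Layer):
    """k x k transposed convolution with stride 2 and "same" padding.

    Implemented as the adjoint of a stride-2 convolution: the output is
    2H x 2W and each input pixel scatters a k x k stamp.  No batch
    normalization follows these layers in the model family.
    """

    def __init__(self, cin, cout, k=3, rng=None):
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        rng = rng or np.random.default_rng(0)
        self.W = he_normal(rng, (k, k, cin, cout), fan_in=k * k * cin)
        self.b = np.zeros(cout, dtype=np.float32)
        self.params = [self.W, self.b]
        self.param_names = ["W", "b"]
        self.grads = [np.zeros_like(p) for p in self.params]
        self._x = None

    def forward(self, x, training=False):
        self._x = x
        n, h, w, _ = x.shape
        k, cout = self.k, self.cout
        H, Wd = 2 * h, 2 * w
        yp = np.zeros((n, H + k - 1, Wd + k - 1, cout), dtype=np.float32)
        xf = x.reshape(-1, self.cin)
        for di in range(k):
            for dj in range(k):
                stamp = (xf @ self.W[di, dj]).reshape(n, h, w, cout)
                yp[:, di:di + H:2, dj:dj + Wd:2, :] += stamp
        y = yp[:, :H, :Wd, :] + self.b
        return y

    def backward(self, dy):
        x = self._x
        n, h, w, _ = x.shape
        k = self.k
        H, Wd = 2 * h, 2 * w
        dyp = np.zeros((n, H + k - 1, Wd + k - 1, self.cout), dtype=np.float32)
        dyp[:, :H, :Wd, :] = dy
        self.grads[1] += dy.reshape(-1, self.cout).sum(axis=0)
        xf = x.reshape(-1, self.cin)
        dx = np.zeros_like(x)
        for di in range(k):
            for dj in range(k):
                patch = dyp[:, di:di + H:2, dj:dj + Wd:2, :].reshape(-1, self.cout)
                self.grads[0][di, dj] += xf.T @ patch
                dx += (patch @ self.W[di, dj].T).reshape(x.shape)
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalization with moving statistics."""

    def __init__(self, c, momentum=0.9, eps=1e-3):
        super().__init__()
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.moving_mean = np.zeros(c, dtype=np.float32)
        self.moving_var = np.ones(c, dtype=np.float32)
        self.params = [self.gamma, self.beta]
        self.param_names = ["gamma", "beta"]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.momentum, self.eps = momentum, eps
        self._cache = None

    @property
    def n_params(self):
        # moving statistics count toward the total (non-trainable)
        return self.gamma.size * 4

    def forward(self, x, training=False):
        if training:
            xr = x.reshape(-1, x.shape[-1])
            m = xr.shape[0]
            mu = xr.mean(axis=0)
            var = np.einsum("ij,ij->j", xr, xr) / m - mu * mu
            np.maximum(var, 0.0, out=var)
            self.moving_mean += (1 - self.momentum) * (mu - self.moving_mean)
            self.moving_var += (1 - self.momentum) * (var - self.moving_var)
        else:
            mu, var = self.moving_mean, self.moving_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype, copy=False)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv, training, x.shape)
        return self.gamma * xhat + self.beta

    def backward(self, dy):
        xhat, inv, training, shape = self._cache
        self.grads[0] += (dy * xhat).sum(axis=(0, 1, 2))
        self.grads[1] += dy.sum(axis=(0, 1, 2))
        if not training:
            return dy * (self.gamma * inv)
        dxhat = dy * self.gamma
        dx = (dxhat - dxhat.mean(axis=(0, 1, 2))
              - xhat * (dxhat * xhat).mean(axis=(0, 1, 2))) * inv
        return dx


class ReLU(Layer):
    def __init__(self):
        super().__init__()
        self._y = None

    def forward(self, x, training=False):
        self._y = np.maximum(x, 0.0)
        return self._y

    def backward(self, dy):
        return dy * (self._y > 0)


class Sigmoid(Layer):
    def __init__(self):
        super().__init__()
        self._y = None

    def forward(self, x, training=False):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy):
        y = self._y
        return dy * y * (1.0 - y)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (inputs have even spatial dims)."""

    def __init__(self):
        super().__init__()
        self._cache = None

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        win = xr.transpose(0, 1, 3, 5, 2, 4).reshape(n, h // 2, w // 2, c, 4)
        idx = win.argmax(axis=-1)
        y = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape)
        return np.ascontiguousarray(y)

    def backward(self, dy):
        idx, shape = self._cache
        n, h, w, c = shape
        dwin = np.zeros((n, h // 2, w // 2, c, 4), dtype=np.float32)
        np.put_along_axis(dwin, idx[..., None], dy[..., None], axis=-1)
        dx = dwin.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return np.ascontiguousarray(dx.reshape(shape))


class UpSample2(Layer):
    """Parameter-free 2x nearest-neighbour upsampling."""

    def forward(self, x, training=False):
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dy):
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate, rng=None):
        super().__init__()
        self.rate = float(rate)
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x, training=False):
        if not training or self.rate <= 0.0:
            self._mask = None
            return x
        keep = np.float32(1.0 - self.rate)
        u = self.rng.random(x.shape, dtype=np.float32)
        self._mask = u < keep          # bool; scaling folded into the product
        y = x * self._mask
        y *= np.float32(1.0) / keep
        return y

    def backward(self, dy):
        if self._mask is None:
            return dy
        dx = dy * self._mask
        dx *= np.float32(1.0 / (1.0 - self.rate))
        return dx


class ChannelAttention(Layer):
    """Channel attention with weights bounded to [0.5, 1).

    Global average pooling over space, one dense C -> C map with bias,
    then ReLU followed by the logistic function.  Because the logistic is
    applied to a rectified (non-negative) pre-activation, every channel
    weight lies in [0.5, 1): low-priority channels are damped by at most
    a factor of two rather than being zeroed out.
    """

    def __init__(self, c, rng=None):
        super().__init__()
        self.c = c
        rng = rng or np.random.default_rng(0)
        self.W = he_normal(rng, (c, c), fan_in=c)
        self.b = np.zeros(c, dtype=np.float32)
        self.params = [self.W, self.b]
        self.param_names = ["W", "b"]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._cache = None

    def weights_for(self, x):
        """Channel weights w_c in [0.5, 1) for input x (N,H,W,C)."""
        z = x.mean(axis=(1, 2))
        a = z @ self.W + self.b
        r = np.maximum(a, 0.0)
        return 1.0 / (1.0 + np.exp(-r))

    def forward(self, x, training=False):
        z = x.mean(axis=(1, 2))              # (N, C)
        a = z @ self.W + self.b
        r = np.maximum(a, 0.0)
        s = 1.0 / (1.0 + np.exp(-r))
        self._cache = (x, z, a, s)
        return x * s[:, None, None, :]

    def backward(self, dy):
        x, z, a, s = self._cache
        n, h, w, c = x.shape
        ds = (dy * x).sum(axis=(1, 2))
        dr = ds * s * (1.0 - s)
        da = np.where(a > 0, dr, 0.0)
        self.grads[0] += z.T @ da
        self.grads[1] += da.sum(axis=0)
        dz = da @ self.W.T
        dx = dy * s[:, None, None, :]
        dx += dz[:, None, None, :] / (h * w)
        return dx


class Add(Layer):
    """Elementwise add of two inputs (used for skip connections)."""

    def forward(self, a, b):
        return a + b

    def backward(self, dy):
        return dy, dy


class Concat(Layer):
    """Channel concatenation of two inputs."""

    def __init__(self):
        super().__init__()
        self._split = None

    def forward(self, a, b):
        self._split = a.shape[-1]
        return np.concatenate([a, b], axis=-1)

    def backward(self, dy):
        s = self._split
        return dy[..., :s], dy[..., s:]


class Adam:
    """Adaptive-moment gradient descent (Kingma & Ba)."""

    def __init__(self, layers, lr=1e-4, beta1=0.9, beta2=0.99, eps=1e-7):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [[np.zeros_like(p) for p in l.params] for l in self.layers]
        self.v = [[np.zeros_like(p) for p in l.params] for l in self.layers]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for li, layer in enumerate(self.layers):
            for pi, (p, g) in enumerate(zip(layer.params, layer.grads)):
                m = self.m[li][pi]
                v = self.v[li][pi]
                m += (1 - b1) * (g - m)
                v += (1 - b2) * (g * g - v)
                p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()
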