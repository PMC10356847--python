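"""Minimal trainable neural-network primitives on numpy.

Layers follow the conventional forward/backward contract: ``forward`` caches
whatever the gradient needs, ``backward`` consumes the upstream gradient and
accumulates parameter gradients in ``grads``.  Tensors are NCHW.  The scope
is exactly what the centerline detector requires — strided convolution,
batch normalization, ReLU, average pooling, residual blocks and dense
layers — with an Adam optimizer and HDF5 (de)serialization of parameters.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv2d", "BatchNorm", "ReLU", "AvgPool2d", "Dense",
    "Sequential", "ResidualBlock", "Adam", "sigmoid",
    "collect_params", "save_params", "load_params",
]


def sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError

    def zero_grad(self):
        for k in self.grads:
            self.grads[k][...] = 0.0

    def children(self):
        return []

    def __call__(self, x, train=True):
        return self.forward(x, train)


def _im2col(x, kh, kw, stride, pad):
    """(N, C, H, W) -> (N, out_h, out_w, C*kh*kw) patch matrix."""
    N, C, H, W = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # (N, C, oh, ow, kh, kw)
    N, C, oh, ow, _, _ = windows.shape
    return windows.transpose(0, 2, 3, 1, 4, 5).reshape(N, oh, ow, C * kh * kw)


def _col2im(dcol, x_shape, kh, kw, stride, pad):
    """Adjoint of _im2col."""
    N, C, H, W = x_shape
    Hp, Wp = H + 2 * pad, W + 2 * pad
    dx = np.zeros((N, C, Hp, Wp))
    oh, ow = dcol.shape[1], dcol.shape[2]
    dcol = dcol.reshape(N, oh, ow, C, kh, kw)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += \
                dcol[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    if pad:
        dx = dx[:, :, pad:Hp - pad, pad:Wp - pad]
    return dx


class Conv2d(Layer):
    """2D convolution with 'same'-style zero padding (pad = k//2)."""

    def __init__(self, c_in, c_out, ksize=3, stride=1, rng=None, bias=True):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = c_in * ksize * ksize
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.params["W"] = rng.standard_normal((c_out, fan_in)) * scale
        self.grads["W"] = np.zeros_like(self.params["W"])
        if bias:
            self.params["b"] = np.zeros(c_out)
            self.grads["b"] = np.zeros(c_out)
        self.ksize, self.stride, self.pad = ksize, stride, ksize // 2
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x, train=True):
        self._x_shape = x.shape
        col = _im2col(x, self.ksize, self.ksize, self.stride, self.pad)
        self._col = col
        out = col @ self.params["W"].T
        if "b" in self.params:
            out = out + self.params["b"]
        return out.transpose(0, 3, 1, 2)

    def backward(self, dy):
        dy = dy.transpose(0, 2, 3, 1)  # (N, oh, ow, c_out)
        self.grads["W"] += np.tensordot(dy, self._col, axes=([0, 1, 2], [0, 1, 2]))
        if "b" in self.params:
            self.grads["b"] += dy.sum(axis=(0, 1, 2))
        dcol = dy @ self.params["W"]
        return _col2im(dcol, self._x_shape, self.ksize, self.ksize,
                       self.stride, self.pad)


class BatchNorm(Layer):
    """Batch normalization over all axes except the channel axis.

    Works for NCHW tensors (``axis=1``) and dense (N, F) tensors (``axis=1``
    with 2-d input).  Keeps running statistics for evaluation mode.
    """

    def __init__(self, channels, momentum=0.9, eps=1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.grads["gamma"] = np.zeros(channels)
        self.grads["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps

    def _bshape(self, x):
        shape = [1] * x.ndim
        shape[1] = -1
        return shape

    def forward(self, x, train=True):
        axes = tuple(i for i in range(x.ndim) if i != 1)
        shape = self._bshape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean.reshape(shape)) * self._istd.reshape(shape)
        self._axes = axes
        self._n = x.size // x.shape[1]
        self._train = train
        return self.params["gamma"].reshape(shape) * self._xhat \
            + self.params["beta"].reshape(shape)

    def backward(self, dy):
        shape = self._bshape(dy)
        axes = self._axes
        self.grads["gamma"] += (dy * self._xhat).sum(axis=axes)
        self.grads["beta"] += dy.sum(axis=axes)
        dxhat = dy * self.params["gamma"].reshape(shape)
        if not self._train:
            return dxhat * self._istd.reshape(shape)
        n = self._n
        term = (dxhat - dxhat.mean(axis=axes).reshape(shape)
                - self._xhat * (dxhat * self._xhat).mean(axis=axes).reshape(shape))
        return term * self._istd.reshape(shape)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class AvgPool2d(Layer):
    """Non-overlapping 2×2 average pooling (input H, W must be even)."""

    def forward(self, x, train=True):
        N, C, H, W = x.shape
        self._shape = x.shape
        return x.reshape(N, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))

    def backward(self, dy):
        N, C, H, W = self._shape
        dx = np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) / 4.0
        return dx


class Dense(Layer):
    """Fully connected layer on (N, F) tensors."""

    def __init__(self, f_in, f_out, rng=None, scale=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        if scale is None:
            scale = np.sqrt(2.0 / f_in)
        self.params["W"] = rng.standard_normal((f_out, f_in)) * scale
        self.params["b"] = np.zeros(f_out)
        self.grads["W"] = np.zeros_like(self.params["W"])
        self.grads["b"] = np.zeros(f_out)

    def forward(self, x, train=True):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dy):
        self.grads["W"] += dy.T @ self._x
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"]


class Sequential(Layer):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def children(self):
        return self.layers


class ResidualBlock(Layer):
    """Pre-activation-free basic block: conv-bn-relu-conv-bn + shortcut."""

    def __init__(self, c_in, c_out, stride=1, rng=None):
        super().__init__()
        self.conv1 = Conv2d(c_in, c_out, 3, stride, rng, bias=False)
        self.bn1 = BatchNorm(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, 1, rng, bias=False)
        self.bn2 = BatchNorm(c_out)
        self.relu2 = ReLU()
        if stride != 1 or c_in != c_out:
            self.shortcut = Sequential(Conv2d(c_in, c_out, 1, stride, rng,
                                              bias=False), BatchNorm(c_out))
        else:
            self.shortcut = None

    def forward(self, x, train=True):
        out = self.bn1(self.conv1(x, train), train)
        out = self.relu1(out, train)
        out = self.bn2(self.conv2(out, train), train)
        sc = x if self.shortcut is None else self.shortcut(x, train)
        return self.relu2(out + sc, train)

    def backward(self, dy):
        dy = self.relu2.backward(dy)
        d_main = self.bn2.backward(dy)
        d_main = self.conv2.backward(d_main)
        d_main = self.relu1.backward(d_main)
        d_main = self.bn1.backward(d_main)
        d_main = self.conv1.backward(d_main)
        d_sc = dy if self.shortcut is None else self.shortcut.backward(dy)
        return d_main + d_sc

    def children(self):
        out = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2,
               self.relu2]
        if self.shortcut is not None:
            out.append(self.shortcut)
        return out


def _walk(layer, prefix="root"):
    yield prefix, layer
    for i, child in enumerate(layer.children()):
        yield from _walk(child, f"{prefix}.{i}")


def collect_params(root: Layer):
    """Flat list of (name, layer, key) for every parameter under ``root``."""
    out = []
    for name, layer in _walk(root):
        for key in layer.params:
            out.append((f"{name}:{key}", layer, key))
    return out


def save_params(root: Layer, h5group):
    for name, layer, key in collect_params(root):
        h5group.create_dataset(name, data=layer.params[key])
    for name, layer in _walk(root):
        if isinstance(layer, BatchNorm):
            h5group.create_dataset(f"{name}:running_mean",
                                   data=layer.running_mean)
            h5group.create_dataset(f"{name}:running_var",
                                   data=layer.running_var)


def load_params(root: Layer, h5group):
    for name, layer, key in collect_params(root):
        layer.params[key][...] = h5group[name][:]
    for name, layer in _walk(root):
        if isinstance(layer, BatchNorm):
            layer.running_mean[...] = h5group[f"{name}:running_mean"][:]
            layer.running_var[...] = h5group[f"{name}:running_var"][:]


class Adam:
    """Adam optimizer over the parameters of one or more layer trees."""

    def __init__(self, roots, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        if isinstance(roots, Layer):
            roots = [roots]
        self.entries = [e for r in roots for e in collect_params(r)]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[key])
                  for _, layer, key in self.entries]
        self.v = [np.zeros_like(layer.params[key])
                  for _, layer, key in self.entries]

    def zero_grad(self):
        for _, layer, key in self.entries:
            layer.grads[key][...] = 0.0

    def step(self, lr=None):
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for i, (_, layer, key) in enumerate(self.entries):
            g = layer.grads[key]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            layer.params[key] -= lr * (self.m[i] / bc1) / (
                np.sqrt(self.v[i] / bc2) + self.eps)
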