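"""Numpy neural-network layers with explicit forward/backward passes.

Everything operates on arrays shaped ``(batch, channels, length)``.  Each
layer caches what its backward pass needs during forward; ``backward``
accumulates parameter gradients into ``Parameter.grad`` and returns the
gradient with respect to its input.  This is a deliberately small,
deterministic engine — no graph tracing, a fixed layer vocabulary — sized
for 1D sequence detectors trained on a CPU.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    """A trainable array plus its accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def xavier_normal(shape: tuple[int, ...], fan_in: int, fan_out: int, rng: np.random.Generator, dtype) -> np.ndarray:
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, std, size=shape).astype(dtype)


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    """Strided 1D convolution (cross-correlation) with 'same'-style padding.

    Output length is ``ceil(L / stride)``; with L divisible by the stride
    this realizes the exact integer downsampling factors of the detector.
    Implemented as im2col + matmul; the input-gradient scatter loops over
    the kernel taps (<= kernel_size strided slice additions), never over
    positions.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, rng: np.random.Generator | None = None,
                 dtype=np.float32, name: str = "conv"):
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        fan_in = in_channels * kernel_size
        fan_out = out_channels * kernel_size
        w = xavier_normal((out_channels, in_channels, kernel_size), fan_in, fan_out, rng, dtype)
        self.weight = Parameter(f"{name}.weight", w)
        self.bias = Parameter(f"{name}.bias", np.zeros(out_channels, dtype=dtype))
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def _pad_amount(self, L: int) -> tuple[int, int, int]:
        L_out = -(-L // self.stride)  # ceil
        pad_total = max((L_out - 1) * self.stride + self.kernel_size - L, 0)
        return L_out, pad_total // 2, pad_total - pad_total // 2

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, C, L = x.shape
        k, s = self.kernel_size, self.stride
        L_out, pl, pr = self._pad_amount(L)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        # (B, C, L_out, k) — k strided views stacked on the last axis
        cols = np.stack([xp[:, :, j : j + s * L_out : s] for j in range(k)], axis=-1)
        cols2d = cols.transpose(0, 2, 1, 3).reshape(B, L_out, C * k)
        wmat = self.weight.value.reshape(self.out_channels, C * k).T
        y = cols2d @ wmat + self.bias.value
        if train:
            self._cache = (cols2d, x.shape, (pl, pr), L_out)
        return y.transpose(0, 2, 1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols2d, (B, C, L), (pl, pr), L_out = self._cache
        k, s = self.kernel_size, self.stride
        dyt = dy.transpose(0, 2, 1)  # (B, L_out, Cout)
        self.weight.grad += np.tensordot(dyt, cols2d, axes=([0, 1], [0, 1])).reshape(self.weight.value.shape)
        self.bias.grad += dyt.sum(axis=(0, 1))
        wmat = self.weight.value.reshape(self.out_channels, C * k)
        dcols2d = dyt @ wmat  # (B, L_out, C*k)
        dcols = dcols2d.reshape(B, L_out, C, k).transpose(0, 2, 1, 3)  # (B,C,L_out,k)
        dxp = np.zeros((B, C, L + pl + pr), dtype=dy.dtype)
        for j in range(k):
            dxp[:, :, j : j + s * L_out : s] += dcols[:, :, :, j]
        return dxp[:, :, pl : pl + L]


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32, name: str = "bn"):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(f"{name}.gamma", np.ones(channels, dtype=dtype))
        self.beta = Parameter(f"{name}.beta", np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None]) * inv_std[None, :, None]
        if train:
            self._cache = (xhat, inv_std.astype(x.dtype))
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2))
        self.beta.grad += dy.sum(axis=(0, 2))
        dxhat = dy * self.gamma.value[None, :, None]
        m1 = dxhat.mean(axis=(0, 2), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(0, 2), keepdims=True)
        return inv_std[None, :, None] * (dxhat - m1 - xhat * m2)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self) -> list[Parameter]:
        return [p for l in self.layers for p in l.parameters()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class ResidualBlock(Layer):
    """Two convolutions (the first strided by the downsampling factor) with
    batch norm and ReLU, plus a strided 1x1 projection shortcut; the branch
    sum passes through a final ReLU."""

    def __init__(self, in_channels: int, out_channels: int, factor: int,
                 kernel_size: int = 9, rng: np.random.Generator | None = None,
                 dtype=np.float32, name: str = "res"):
        rng = rng or np.random.default_rng(0)
        self.main = Sequential(
            Conv1d(in_channels, out_channels, kernel_size, stride=factor, rng=rng, dtype=dtype, name=f"{name}.conv1"),
            BatchNorm1d(out_channels, dtype=dtype, name=f"{name}.bn1"),
            ReLU(),
            Conv1d(out_channels, out_channels, kernel_size, stride=1, rng=rng, dtype=dtype, name=f"{name}.conv2"),
            BatchNorm1d(out_channels, dtype=dtype, name=f"{name}.bn2"),
        )
        self.shortcut = Conv1d(in_channels, out_channels, 1, stride=factor, rng=rng, dtype=dtype, name=f"{name}.proj")
        self.relu = ReLU()

    def parameters(self) -> list[Parameter]:
        return self.main.parameters() + self.shortcut.parameters()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.relu.forward(
            self.main.forward(x, train=train) + self.shortcut.forward(x, train=train),
            train=train,
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.relu.backward(dy)
        return self.main.backward(d) + self.shortcut.backward(d)


class DetectionHead(Layer):
    """Map the final ``(B, 22, C_cells)`` feature map to bounded predictions
    ``(B, C_cells, 22)``: logistic on presence/start/length, softmax over the
    type group and separately over the lineage group."""

    def __init__(self, n_types: int, n_lineages: int):
        self.n_types = n_types
        self.n_lineages = n_lineages
        self._cache = None

    @staticmethod
    def _softmax(z: np.ndarray) -> np.ndarray:
        z = z - z.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        z = x.transpose(0, 2, 1)  # (B, C_cells, 22)
        y = np.empty_like(z)
        y[..., :3] = 1.0 / (1.0 + np.exp(-z[..., :3]))
        t = slice(3, 3 + self.n_types)
        g = slice(3 + self.n_types, 3 + self.n_types + self.n_lineages)
        y[..., t] = self._softmax(z[..., t])
        y[..., g] = self._softmax(z[..., g])
        if train:
            self._cache = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        y = self._cache
        dz = np.empty_like(y)
        dz[..., :3] = dy[..., :3] * y[..., :3] * (1.0 - y[..., :3])
        for grp in (slice(3, 3 + self.n_types),
                    slice(3 + self.n_types, 3 + self.n_types + self.n_lineages)):
            yg = y[..., grp]
            dg = dy[..., grp]
            dz[..., grp] = yg * (dg - (dg * yg).sum(axis=-1, keepdims=True))
        return dz.transpose(0, 2, 1)
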