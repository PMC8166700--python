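"""Minimal NumPy neural-network core for small fully-convolutional models.

Every layer follows an explicit ``forward(x, train)`` / ``backward(gy)``
protocol on float32 arrays in NCHW layout.  Gradients accumulate into
``Param.grad``; the graph is small and static, so back-propagation is run
by the model in exact reverse order of the forward pass rather than through
a tape.  Analytic gradients are verified against central finite differences
in the test suite.
"""

from __future__ import annotations

import numpy as np

#: working dtype; float64 is used by the numeric gradient checks
DTYPE = np.float32

__all__ = [
    "DTYPE",
    "Param",
    "Conv2D",
    "BatchNorm",
    "ReLU",
    "MaxPool2",
    "UpNearest2",
    "BilinearResize",
    "softmax_channels",
    "softmax_backward",
    "Adam",
]


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Conv2D:
    """2-D convolution with square kernels, 'same' zero padding, no bias.

    Kernels are bias-free throughout the package: the batch-normalization
    shift plays the role of the bias, and the parameter-counting convention
    of the architecture algebra counts kernel elements only.

    Parameters
    ----------
    cin, cout : int
        Input / output channel counts.
    ksize : int
        Kernel side (1 or 3 in this package).
    dilation : int
        Hole spacing; ``dilation=1`` is an ordinary convolution.  Dilation
        adds no weights.
    """

    def __init__(self, cin: int, cout: int, ksize: int = 3, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        if dilation < 1:
            raise ValueError("dilation_rate must be >= 1")
        self.cin, self.cout, self.ksize, self.dilation = cin, cout, ksize, dilation
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = cin * ksize * ksize
        w = rng.standard_normal((cout, cin, ksize, ksize)) * np.sqrt(2.0 / fan_in)
        self.weight = Param(w, name=f"conv{ksize}x{ksize}_{cin}->{cout}")
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        k, d = self.ksize, self.dilation
        pad = d * (k // 2)
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
        out = np.zeros((n, self.cout, h, w), dtype=DTYPE)
        W = self.weight.value
        out2 = out.reshape(n, self.cout, h * w)
        for i in range(k):
            for j in range(k):
                xs = xp[:, :, i * d:i * d + h, j * d:j * d + w]
                out2 += np.matmul(W[:, :, i, j], xs.reshape(n, c, h * w))
        self._cache = (xp, x.shape, pad)
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xp, xshape, pad = self._cache
        n, c, h, w = xshape
        k, d = self.ksize, self.dilation
        W = self.weight.value
        gxp = np.zeros_like(xp)
        gy2 = gy.reshape(n, self.cout, h * w)
        for i in range(k):
            for j in range(k):
                xs = xp[:, :, i * d:i * d + h, j * d:j * d + w]
                self.weight.grad[:, :, i, j] += np.tensordot(
                    gy, xs, axes=([0, 2, 3], [0, 2, 3]))
                gxp[:, :, i * d:i * d + h, j * d:j * d + w] += np.matmul(
                    W[:, :, i, j].T, gy2).reshape(n, c, h, w)
        if pad:
            return gxp[:, :, pad:-pad, pad:-pad]
        return gxp

    def params(self) -> list[Param]:
        return [self.weight]


class BatchNorm:
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels), name=f"bn_gamma_{channels}")
        self.beta = Param(np.zeros(channels), name=f"bn_beta_{channels}")
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        g = self.gamma.value[None, :, None, None]
        b = self.beta.value[None, :, None, None]
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
            ivar = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None, None]) * ivar[None, :, None, None]
            self._cache = (xhat, ivar)
            return (g * xhat + b).astype(DTYPE)
        ivar = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean[None, :, None, None]) * ivar[None, :, None, None]
        self._cache = None
        return (g * xhat + b).astype(DTYPE)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward through BatchNorm requires a train-mode forward")
        xhat, ivar = self._cache
        n, c, h, w = gy.shape
        m = n * h * w
        self.beta.grad += gy.sum(axis=(0, 2, 3))
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2, 3))
        gxhat = gy * self.gamma.value[None, :, None, None]
        s1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        gx = (ivar[None, :, None, None] / m) * (m * gxhat - s1 - xhat * s2)
        return gx.astype(DTYPE)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(DTYPE)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, 0.0).astype(DTYPE)

    def params(self) -> list[Param]:
        return []


class MaxPool2:
    """2x2 max pooling with stride 2; ties resolve to the first maximum."""

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2 requires even spatial dimensions")
        xw = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xw = xw.reshape(n, c, h // 2, w // 2, 4)
        idx = xw.argmax(axis=-1)
        out = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape)
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        idx, xshape = self._cache
        n, c, h, w = xshape
        gw = np.zeros((n, c, h // 2, w // 2, 4), dtype=DTYPE)
        np.put_along_axis(gw, idx[..., None], gy[..., None], axis=-1)
        gw = gw.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return gw.reshape(n, c, h, w)

    def params(self) -> list[Param]:
        return []


class UpNearest2:
    """Nearest-neighbour up-pooling by a factor of 2 (weight-free)."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, h, w = gy.shape
        return gy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))

    def params(self) -> list[Param]:
        return []


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Bilinear interpolation matrix (n_out, n_in), half-pixel convention."""
    M = np.zeros((n_out, n_in), dtype=DTYPE)
    scale = n_in / n_out
    src = (np.arange(n_out) + 0.5) * scale - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    t = (src - lo).astype(DTYPE)
    M[np.arange(n_out), lo] += 1 - t
    M[np.arange(n_out), hi] += t
    return M


class BilinearResize:
    """Differentiable bilinear resize to a fixed output shape (separable)."""

    def __init__(self, out_shape: tuple[int, int]):
        self.out_shape = out_shape
        self._mats: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
        self._in_shape = None

    def _matrices(self, h: int, w: int):
        key = (h, w)
        if key not in self._mats:
            oh, ow = self.out_shape
            self._mats[key] = (_interp_matrix(oh, h), _interp_matrix(ow, w))
        return self._mats[key]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        Mh, Mw = self._matrices(h, w)
        self._in_shape = (h, w)
        t = np.einsum("oh,nchw->ncow", Mh, x, optimize=True)
        return np.einsum("pw,ncow->ncop", Mw, t, optimize=True)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        h, w = self._in_shape
        Mh, Mw = self._matrices(h, w)
        t = np.einsum("pw,ncop->ncow", Mw, gy, optimize=True)
        return np.einsum("oh,ncow->nchw", Mh, t, optimize=True).astype(DTYPE)

    def params(self) -> list[Param]:
        return []


def softmax_channels(z: np.ndarray) -> np.ndarray:
    """Softmax across the channel axis of an NCHW array."""
    zm = z - z.max(axis=1, keepdims=True)
    e = np.exp(zm)
    return (e / e.sum(axis=1, keepdims=True)).astype(DTYPE)


def softmax_backward(p: np.ndarray, gp: np.ndarray) -> np.ndarray:
    """Gradient through the channel softmax: ``gz = p * (gp - sum(gp * p))``."""
    inner = (gp * p).sum(axis=1, keepdims=True)
    return (p * (gp - inner)).astype(DTYPE)


class Adam:
    """Adam optimizer over a list of :class:`Param`.

    ``lr_fn`` maps the (0-based) iteration index to the learning rate, which
    lets the caller install the staircase decay schedule.
    """

    def __init__(self, params: list[Param], lr_fn, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr_fn = lr_fn
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def step(self) -> float:
        lr = float(self.lr_fn(self.t))
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1 - b1 ** self.t
        c2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
        return lr

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
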