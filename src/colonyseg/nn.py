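"""Compact NumPy convolutional-network engine.

Implements exactly the layers the segmentation U-Net needs -- 3x3
convolution, batch normalization, ReLU, 2x2 max pooling, stride-2 transposed
convolution, channel concatenation -- with hand-derived backward passes, plus
the Adam and Ranger (RAdam + Lookahead) optimizers.  Convolutions are
evaluated as k*k channel-mixing matrix products on shifted views of the
padded input so the heavy lifting stays inside BLAS without materializing
an im2col patch matrix.

Tensors are float32 arrays in NCHW layout.  The engine is deliberately
minimal: fixed stride-1 convolutions, manual graph wiring by the model
class, no autograd.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "ConvTranspose2x",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2",
    "Adam",
    "RAdam",
    "Lookahead",
    "ranger",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


# ---------------------------------------------------------------------------
# low-level convolution kernels (stride 1, valid, on pre-padded input)
#
# A kxk correlation is evaluated as k*k channel-mixing matrix products on
# shifted views of the padded input ("shift-and-matmul").  This keeps the
# working set small (no im2col patch matrix) and the products inside BLAS.
# ---------------------------------------------------------------------------


def _conv_valid(xp: np.ndarray, weight: np.ndarray) -> np.ndarray:
    """Valid stride-1 correlation of pre-padded ``xp`` with ``weight``
    (F, C, k, k); returns (N, F, Ho, Wo)."""
    n, c, h, w = xp.shape
    f, _, k, _ = weight.shape
    ho, wo = h - k + 1, w - k + 1
    acc = np.zeros((f, n, ho, wo), np.float32)
    for di in range(k):
        for dj in range(k):
            xs = xp[:, :, di : di + ho, dj : dj + wo]
            acc += np.tensordot(weight[:, :, di, dj], xs, axes=([1], [1]))
    return np.ascontiguousarray(acc.transpose(1, 0, 2, 3))


def _conv_dw(xp: np.ndarray, dy: np.ndarray, k: int) -> np.ndarray:
    """Weight gradient: correlate the pre-padded input with the output
    gradient.  Returns (F, C, k, k)."""
    n, f, ho, wo = dy.shape
    c = xp.shape[1]
    dyf = np.ascontiguousarray(dy.transpose(1, 0, 2, 3)).reshape(f, -1)
    dw = np.empty((f, c, k, k), np.float32)
    for di in range(k):
        for dj in range(k):
            xs = xp[:, :, di : di + ho, dj : dj + wo]
            xf = np.ascontiguousarray(xs.transpose(1, 0, 2, 3)).reshape(c, -1)
            dw[:, :, di, dj] = dyf @ xf.T
    return dw


def _flip_swap(weight: np.ndarray) -> np.ndarray:
    """(F,C,k,k) -> (C,F,k,k) with spatially flipped kernels."""
    return np.ascontiguousarray(weight.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])


def _pad2(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return np.asarray(x, np.float32)
    return np.pad(np.asarray(x, np.float32), ((0, 0), (0, 0), (p, p), (p, p)))


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Conv2d:
    """3x3 (or 1x1) stride-1 convolution with 'same' padding."""

    def __init__(self, cin: int, cout: int, k: int = 3, bias: bool = True, rng=None):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (cin * k * k))  # He initialization
        self.weight = Param(rng.standard_normal((cout, cin, k, k)) * std)
        self.bias = Param(np.zeros(cout)) if bias else None
        self.k = k
        self.pad = (k - 1) // 2
        self._xp = None

    @property
    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        xp = _pad2(x, self.pad)
        self._xp = xp if train else None
        y = _conv_valid(xp, self.weight.value)
        if self.bias is not None:
            y += self.bias.value[None, :, None, None]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = np.ascontiguousarray(dy, dtype=np.float32)
        self.weight.grad += _conv_dw(self._xp, dy, self.k)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        self._xp = None
        # backward-data: full correlation of dy with the flipped kernel;
        # with 'same' padding p, pad dy by k-1-p to land back on the input size
        return _conv_valid(_pad2(dy, self.k - 1 - self.pad), _flip_swap(self.weight.value))


class ConvTranspose2x:
    """Transposed convolution, kernel 3, stride 2: doubles H and W.

    Equivalent to PyTorch ``ConvTranspose2d(cin, cout, 3, stride=2,
    padding=1, output_padding=1)``.  Implemented as zero-stuffing followed by
    a valid correlation with the flipped kernel.
    """

    def __init__(self, cin: int, cout: int, rng=None):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (cin * 9))
        self.weight = Param(rng.standard_normal((cin, cout, 3, 3)) * std)
        self.bias = Param(np.zeros(cout))
        self._xs = None

    @property
    def params(self):
        return [self.weight, self.bias]

    @staticmethod
    def _stuff(x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xs = np.zeros((n, c, 2 * h + 2, 2 * w + 2), np.float32)
        xs[:, :, 1 : 2 * h : 2, 1 : 2 * w : 2] = x
        return xs

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        xs = self._stuff(np.asarray(x, np.float32))
        self._xs = xs if train else None
        self._xshape = x.shape
        wf = _flip_swap(self.weight.value)  # (cout, cin, 3, 3)
        y = _conv_valid(xs, wf)
        return y + self.bias.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = np.ascontiguousarray(dy, dtype=np.float32)
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        dwf = _conv_dw(self._xs, dy, 3)  # gradient of the flipped kernel
        self.weight.grad += _flip_swap(dwf)
        self._xs = None
        # gradient w.r.t. the stuffed input: full correlation of dy with
        # flip_swap(flip_swap(W)) = W itself; then pick the stuffed positions
        dxs = _conv_valid(_pad2(dy, 2), np.ascontiguousarray(self.weight.value))
        h, w = self._xshape[2], self._xshape[3]
        return np.ascontiguousarray(dxs[:, :, 1 : 2 * h : 2, 1 : 2 * w : 2])


class BatchNorm2d:
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, np.float32)
        self.running_var = np.ones(c, np.float32)
        self.momentum = momentum
        self.eps = eps
        self._acc_mean = np.zeros(c, np.float64)
        self._acc_var = np.zeros(c, np.float64)
        self._acc_n = 0

    @property
    def params(self):
        return [self.gamma, self.beta]

    def finalize_epoch_stats(self) -> None:
        """Precise-BN: replace the running statistics by the average of the
        batch statistics seen since the last call.  Eval-mode behavior then
        reflects the epoch's true activation distribution instead of a
        momentum-lagged estimate (which, early in training, collapses
        predictions toward zero and corrupts validation-based scheduling)."""
        if self._acc_n:
            self.running_mean[...] = self._acc_mean / self._acc_n
            self.running_var[...] = self._acc_var / self._acc_n
            self._acc_mean[...] = 0.0
            self._acc_var[...] = 0.0
            self._acc_n = 0

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            self._acc_mean += mean
            self._acc_var += var
            self._acc_n += 1
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._xhat = xhat
            self._inv = inv
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = dy * self.gamma.value[None, :, None, None]
        gs = g.sum(axis=(0, 2, 3))[None, :, None, None]
        gx = (g * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        dx = (g - gs / m - xhat * gx / m) * inv[None, :, None, None]
        self._xhat = None
        return dx.astype(np.float32)


class ReLU:
    params: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mask = x > 0
        if train:
            self._mask = mask
        return x * mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2:
    """2x2 max pooling, stride 2."""

    params: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        xv = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xv = xv.reshape(n, c, h // 2, w // 2, 4)
        idx = xv.argmax(axis=-1)
        y = np.take_along_axis(xv, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
            self._shape = x.shape
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dxv = np.zeros((n, c, h // 2, w // 2, 4), np.float32)
        np.put_along_axis(dxv, self._idx[..., None], dy[..., None].astype(np.float32), axis=-1)
        dx = dxv.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        self._idx = None
        return np.ascontiguousarray(dx)


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------


class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad * p.grad - v)
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0


class RAdam(Adam):
    """Rectified Adam: warms up the adaptive term by variance rectification."""

    def step(self):
        self.t += 1
        b1, b2, t = self.b1, self.b2, self.t
        bc1 = 1.0 - b1**t
        rho_inf = 2.0 / (1.0 - b2) - 1.0
        rho = rho_inf - 2.0 * t * b2**t / (1.0 - b2**t)
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - b1) * (p.grad - m)
            v += (1.0 - b2) * (p.grad * p.grad - v)
            mhat = m / bc1
            if rho > 4.0:
                r = np.sqrt(
                    ((rho - 4.0) * (rho - 2.0) * rho_inf)
                    / ((rho_inf - 4.0) * (rho_inf - 2.0) * rho)
                )
                vhat = np.sqrt(v / (1.0 - b2**t)) + self.eps
                p.value -= self.lr * r * mhat / vhat
            else:
                p.value -= self.lr * mhat


class Lookahead:
    """Lookahead wrapper: every k steps, pull slow weights toward fast ones."""

    def __init__(self, inner, k: int = 6, alpha: float = 0.5):
        self.inner = inner
        self.k = k
        self.alpha = alpha
        self._step = 0
        self._slow = [p.value.copy() for p in inner.params]

    @property
    def params(self):
        return self.inner.params

    @property
    def lr(self):
        return self.inner.lr

    @lr.setter
    def lr(self, value):
        self.inner.lr = value

    def step(self):
        self.inner.step()
        self._step += 1
        if self._step % self.k == 0:
            for p, slow in zip(self.inner.params, self._slow):
                slow += self.alpha * (p.value - slow)
                p.value[...] = slow

    def zero_grad(self):
        self.inner.zero_grad()


def ranger(params, lr: float, k: int = 6, alpha: float = 0.5) -> Lookahead:
    """Ranger optimizer: RAdam wrapped in Lookahead."""
    return Lookahead(RAdam(params, lr=lr), k=k, alpha=alpha)
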