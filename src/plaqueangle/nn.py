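"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package's two predictors are small convolutional networks trained on
desk-scale phantom data, so they run on a deliberately small autograd
engine: dense float64 arrays, stride-1 same-padding convolutions with odd
kernels, factor pooling/upsampling, and an Adam optimizer.  The engine
exposes exactly the operations the plaque models need — it is not a
general deep-learning framework.

Gradients flow through a taped graph of :class:`Tensor` nodes; calling
``backward()`` on a scalar loss topologically sorts the tape and
accumulates ``grad`` on every tensor with ``requires_grad``.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32  # engine precision; reference loss forms use float64
EPS = 1e-6  # probability clipping for binary cross entropy


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out = _node(self.data + other.data, (self, other))

        def bwd(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other)
        out = _node(self.data * other.data, (self, other))

        def bwd(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("tensor/tensor division not supported; multiply by a constant")
        return self * (1.0 / float(other))

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = _node(self.data @ other.data, (self, other))

        def bwd(g):
            self._accumulate(g @ np.swapaxes(other.data, -1, -2))
            other._accumulate(np.swapaxes(self.data, -1, -2) @ g)

        out._backward = bwd
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
    if out.requires_grad:
        out._parents = tuple(p for p in parents if isinstance(p, Tensor))
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


# -- elementwise ----------------------------------------------------------


def relu(x: Tensor) -> Tensor:
    out = _node(np.maximum(x.data, 0.0), (x,))
    mask = x.data > 0
    out._backward = lambda g: x._accumulate(g * mask)
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = _node(s, (x,))
    out._backward = lambda g: x._accumulate(g * s * (1.0 - s))
    return out


def log(x: Tensor) -> Tensor:
    out = _node(np.log(x.data), (x,))
    out._backward = lambda g: x._accumulate(g / x.data)
    return out


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only where unclipped (straight-through
    at the boundaries is deliberately not used)."""
    out = _node(np.clip(x.data, lo, hi), (x,))
    mask = (x.data > lo) & (x.data < hi)
    out._backward = lambda g: x._accumulate(g * mask)
    return out


def absolute(x: Tensor) -> Tensor:
    out = _node(np.abs(x.data), (x,))
    out._backward = lambda g: x._accumulate(g * np.sign(x.data))
    return out


def square(x: Tensor) -> Tensor:
    out = _node(x.data**2, (x,))
    out._backward = lambda g: x._accumulate(g * 2.0 * x.data)
    return out


# -- reductions / shape ---------------------------------------------------


def tsum(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = _node(x.data.sum(axis=axis, keepdims=keepdims), (x,))

    def bwd(g):
        if axis is None:
            x._accumulate(np.broadcast_to(g, x.shape).copy())
        else:
            gg = g if keepdims else np.expand_dims(g, axis)
            x._accumulate(np.broadcast_to(gg, x.shape).copy())

    out._backward = bwd
    return out


def tmean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = x.data.size if axis is None else x.data.shape[axis]
    return tsum(x, axis=axis, keepdims=keepdims) / n


def reshape(x: Tensor, shape) -> Tensor:
    out = _node(x.data.reshape(shape), (x,))
    out._backward = lambda g: x._accumulate(g.reshape(x.shape))
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = _node(data, tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    out._backward = bwd
    return out


# -- structured ops -------------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, C, H, W) zero-padded 'same' -> (N, H*W, C*kh*kw)."""
    n, c, h, w = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # win: (N, C, H, W, kh, kw) -> (N, H*W, C*kh*kw)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * kh * kw)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-1 same-padding 2-D convolution (cross-correlation).

    ``x``: (N, Cin, H, W); ``w``: (Cout, Cin, kh, kw) with odd kh, kw;
    ``b``: (Cout,) or None.
    """
    n, cin, h, wd = x.shape
    cout, cin_w, kh, kw = w.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin}, kernel {cin_w}")
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("kernels must have odd spatial size")
    cols = _im2col(x.data, kh, kw)  # (N, HW, Cin*kh*kw)
    wmat = w.data.reshape(cout, -1)
    out_data = (cols @ wmat.T).transpose(0, 2, 1).reshape(n, cout, h, wd)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = _node(out_data, parents)

    def bwd(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n, h * wd, cout)  # (N, HW, Cout)
        if w.requires_grad:
            gw = np.einsum("npo,npk->ok", gmat, cols)
            w._accumulate(gw.reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # dx = same-padding conv of g with spatially flipped, channel-
            # transposed kernels (valid for odd kernels, stride 1).
            wt = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (Cin, Cout, kh, kw)
            gcols = _im2col(g, kh, kw)
            dx = (gcols @ wt.reshape(cin, -1).T).transpose(0, 2, 1).reshape(x.shape)
            x._accumulate(dx)

    out._backward = bwd
    return out


def avgpool2d(x: Tensor, pool: tuple[int, int]) -> Tensor:
    n, c, h, w = x.shape
    ph, pw = pool
    if h % ph or w % pw:
        raise ValueError(f"pool {pool} does not divide spatial shape {(h, w)}")
    r = x.data.reshape(n, c, h // ph, ph, w // pw, pw)
    out = _node(r.mean(axis=(3, 5)), (x,))

    def bwd(g):
        gg = np.repeat(np.repeat(g, ph, axis=2), pw, axis=3) / (ph * pw)
        x._accumulate(gg)

    out._backward = bwd
    return out


def upsample2d(x: Tensor, factor: tuple[int, int]) -> Tensor:
    """Nearest-neighbour upsampling by integer factors."""
    fh, fw = factor
    out = _node(np.repeat(np.repeat(x.data, fh, axis=2), fw, axis=3), (x,))

    def bwd(g):
        n, c, h, w = x.shape
        gg = g.reshape(n, c, h, fh, w, fw).sum(axis=(3, 5))
        x._accumulate(gg)

    out._backward = bwd
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.shape) < keep) / keep
    out = _node(x.data * mask, (x,))
    out._backward = lambda g: x._accumulate(g * mask)
    return out


def bce(pred: Tensor, target: np.ndarray) -> Tensor:
    """Elementwise binary cross entropy with probability clipping."""
    p = clip(pred, EPS, 1.0 - EPS)
    t = np.asarray(target, dtype=DTYPE)
    return -(Tensor(t) * log(p) + Tensor(1.0 - t) * log(1.0 - p))


# -- modules --------------------------------------------------------------


class Conv2dLayer:
    """3x3 (or 1x1) convolution with He-normal initialization."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (cin * k * k))
        self.w = Tensor(rng.normal(0.0, std, size=(cout, cin, k, k)), requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b)

    @property
    def params(self) -> list[Tensor]:
        return [self.w, self.b]


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
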