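"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package's network blocks (multi-scale residual convolutions, channel
attention, conv-LSTM branches, CBAM fusion) are built from the small set of
differentiable primitives defined here: elementwise arithmetic with
broadcasting, matrix multiplication, reshaping/concatenation/slicing,
reductions (sum / mean / max), pointwise nonlinearities and a same- or
valid-padded 2-D cross-correlation implemented via im2col.

Gradients are accumulated by a topological backward sweep over the recorded
tape.  All arrays are float64; correctness of every composite layer is
checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "cross_entropy_logits", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over broadcast (size-1) axes
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        # topological order of the tape reachable from self
        order, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        for t in order:
            t.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(order):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad = self.grad + g

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bwd(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bwd(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * (Tensor._lift(other) ** -1.0)

    def __rtruediv__(self, other):
        return Tensor._lift(other) * (self ** -1.0)

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _parents=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1.0))
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bwd(g):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            self._accum(_unbroadcast(ga, a.shape))
            other._accum(_unbroadcast(gb, b.shape))

        out._backward = bwd
        return out

    # ------------------------------------------------------------ shape ops
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(old))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bwd
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis, keepdims=False):
        val = self.data.max(axis=axis, keepdims=True)
        out_data = val if keepdims else np.squeeze(val, axis=axis)
        mask = (self.data == val).astype(np.float64)
        mask /= mask.sum(axis=axis, keepdims=True)  # ties share gradient
        out = Tensor(out_data, _parents=(self,))

        def bwd(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(mask * g)

        out._backward = bwd
        return out

    # --------------------------------------------------------- nonlinearities
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _parents=(self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, _parents=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - t * t))
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, _parents=(self,))
        out._backward = lambda g: self._accum(g * e)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out


# ---------------------------------------------------------------- free funcs
def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])

    out._backward = bwd
    return out


def _im2col(xp: np.ndarray, kh: int, kw: int):
    n, c, hp, wp = xp.shape
    ho, wo = hp - kh + 1, wp - kw + 1
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i:i + ho, j:j + wo]
    return cols.reshape(n, c * kh * kw, ho * wo), ho, wo


def _col2im(dcols: np.ndarray, xshape, kh: int, kw: int, ph: int, pw: int):
    n, c, h, w = xshape
    hp, wp = h + 2 * ph, w + 2 * pw
    ho, wo = hp - kh + 1, wp - kw + 1
    dcols = dcols.reshape(n, c, kh, kw, ho, wo)
    dxp = np.zeros((n, c, hp, wp), dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + ho, j:j + wo] += dcols[:, :, i, j]
    return dxp[:, :, ph:hp - ph if ph else hp, pw:wp - pw if pw else wp]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           padding: str = "same") -> Tensor:
    """2-D cross-correlation, stride 1.

    x: [N, C, H, W]; w: [F, C, kh, kw]; b: [F] or None.
    padding "same" keeps H×W; "valid" shrinks to (H-kh+1)×(W-kw+1).
    Same-padding requires odd kernels so the receptive field is centred.
    """
    n, c, h, wd = x.data.shape
    f, c2, kh, kw = w.data.shape
    if c != c2:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {c2}")
    if padding == "same":
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("same-padding requires odd kernel sizes")
        ph, pw = kh // 2, kw // 2
    elif padding == "valid":
        if h < kh or wd < kw:
            raise ValueError(
                f"input {h}x{wd} smaller than kernel {kh}x{kw} with valid padding")
        ph = pw = 0
    else:
        raise ValueError(f"unknown padding {padding!r}")

    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data
    cols, ho, wo = _im2col(xp, kh, kw)
    wmat = w.data.reshape(f, -1)
    out_data = np.matmul(wmat, cols).reshape(n, f, ho, wo)
    if b is not None:
        out_data = out_data + b.data.reshape(1, f, 1, 1)

    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, _parents=parents)

    def bwd(g):
        gmat = g.reshape(n, f, ho * wo)
        w._accum(np.matmul(gmat, cols.transpose(0, 2, 1)).sum(axis=0).reshape(w.data.shape))
        dcols = np.matmul(wmat.T, gmat)
        x._accum(_col2im(dcols, x.data.shape, kh, kw, ph, pw))
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3)))

    out._backward = bwd
    return out


def softmax(logits: Tensor, axis: int = -1) -> Tensor:
    m = logits.data.max(axis=axis, keepdims=True)  # shift-invariant constant
    z = logits - m
    e = z.exp()
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy_logits(logits: Tensor, onehot: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of softmax(logits) under one-hot targets."""
    n = logits.data.shape[0]
    m = logits.data.max(axis=1, keepdims=True)
    z = logits - m
    lse = z.exp().sum(axis=1, keepdims=True).log()
    logp = z - lse
    return -(Tensor(onehot) * logp).sum() * (1.0 / n)
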