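"""Trainable layers built on the autodiff primitives.

Weight initialization is a seeded uniform fan-in scheme: every parameter is
drawn from U(-1/sqrt(fan_in), 1/sqrt(fan_in)) using the numpy Generator the
model was constructed with, so a model is reproducible from its seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    s = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-s, s, size=shape), requires_grad=True)


class Module:
    """Base class: parameter discovery and train/eval mode switching."""

    training: bool = True

    def modules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for u in v:
                    if isinstance(u, Module):
                        yield u

    def named_parameters(self, prefix: str = ""):
        for k, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                yield f"{prefix}{k}", v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{prefix}{k}.")
            elif isinstance(v, (list, tuple)):
                for i, u in enumerate(v):
                    if isinstance(u, Module):
                        yield from u.named_parameters(f"{prefix}{k}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self, flag: bool = True):
        self.training = flag
        for m in self.modules():
            m.train(flag)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict:
        d = {name: p.data.copy() for name, p in self.named_parameters()}
        for k, v in self.__dict__.items():
            if isinstance(v, BatchNorm):
                d[f"{k}.running_mean"] = v.running_mean.copy()
                d[f"{k}.running_var"] = v.running_var.copy()
        # recurse running stats of nested modules
        for k, v in self.__dict__.items():
            if isinstance(v, Module) and not isinstance(v, BatchNorm):
                for name, arr in v.state_dict().items():
                    if name.endswith(("running_mean", "running_var")):
                        d[f"{k}.{name}"] = arr
            elif isinstance(v, (list, tuple)):
                for i, u in enumerate(v):
                    if isinstance(u, Module):
                        for name, arr in u.state_dict().items():
                            if name.endswith(("running_mean", "running_var")):
                                d[f"{k}.{i}.{name}"] = arr
        return d

    def load_state_dict(self, d: dict):
        params = dict(self.named_parameters())
        for name, arr in d.items():
            if name.endswith(("running_mean", "running_var")):
                obj = self
                *path, attr = name.split(".")
                for part in path:
                    obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
                setattr(obj, attr, np.asarray(arr, dtype=np.float64).copy())
            else:
                if name not in params:
                    raise KeyError(f"unexpected parameter {name!r} in checkpoint")
                if params[name].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name!r}")
                params[name].data = np.asarray(arr, dtype=np.float64).copy()


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel, rng: np.random.Generator,
                 padding: str = "same", bias: bool = True):
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        fan_in = in_ch * kh * kw
        self.weight = _uniform(rng, (out_ch, in_ch, kh, kw), fan_in)
        self.bias = _uniform(rng, (out_ch,), fan_in) if bias else None
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding)


class Dense(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        self.weight = _uniform(rng, (in_dim, out_dim), in_dim)
        self.bias = _uniform(rng, (out_dim,), in_dim) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y + self.bias if self.bias is not None else y


class BatchNorm(Module):
    """Per-feature-channel normalization over axis 1.

    Training mode normalizes with batch statistics (gradients flow through
    them); inference mode uses exponential running averages.
    Accepts [N, C] or [N, C, H, W].
    """

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(n_ch), requires_grad=True)
        self.beta = Tensor(np.zeros(n_ch), requires_grad=True)
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        axes = (0,) if x.ndim == 2 else (0, 2, 3)
        shape = (1, -1) if x.ndim == 2 else (1, -1, 1, 1)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(-1)
            inv = (var + self.eps) ** -0.5
            xhat = xc * inv
        else:
            mu = self.running_mean.reshape(shape)
            inv = 1.0 / np.sqrt(self.running_var.reshape(shape) + self.eps)
            xhat = (x - mu) * inv
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class Dropout(Module):
    """Inverted dropout; active only in training mode, driven by the model rng."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * mask


class LSTM(Module):
    """Single-layer LSTM; consumes [N, L, D] and returns the final hidden state [N, H]."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.wx = _uniform(rng, (in_dim, 4 * hidden), in_dim)
        self.wh = _uniform(rng, (hidden, 4 * hidden), hidden)
        self.b = _uniform(rng, (4 * hidden,), in_dim + hidden)

    def __call__(self, x: Tensor) -> Tensor:
        n, length, _ = x.shape
        hdim = self.hidden
        h = Tensor(np.zeros((n, hdim)))
        c = Tensor(np.zeros((n, hdim)))
        for t in range(length):
            xt = x[:, t, :]
            z = xt @ self.wx + h @ self.wh + self.b
            i = z[:, 0 * hdim:1 * hdim].sigmoid()
            f = z[:, 1 * hdim:2 * hdim].sigmoid()
            g = z[:, 2 * hdim:3 * hdim].tanh()
            o = z[:, 3 * hdim:4 * hdim].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
        return h


class SGD:
    """Plain stochastic gradient descent (momentum 0, no weight decay)."""

    def __init__(self, params, lr: float):
        self.params = list(params)
        self.lr = lr

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.data = p.data - self.lr * p.grad
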