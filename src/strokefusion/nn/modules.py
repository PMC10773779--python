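"""Neural-network building blocks on top of the autograd engine.

Layers mirror the usual deep-learning vocabulary (Linear, Conv2d,
BatchNorm, LayerNorm, Dropout, multi-head self-attention) with explicit
seeded initialisation: every module takes a ``numpy.random.Generator`` so
that construction is a pure function of the seed.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat, conv2d

__all__ = ["Module", "Linear", "Conv2d", "BatchNorm1d", "BatchNorm2d",
           "LayerNorm", "Dropout", "MultiheadSelfAttention", "Sequential",
           "Adam"]


class Module:
    """Base class: tracks parameters, submodules and train/eval mode."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self):
        for m in self.modules():
            object.__setattr__(m, "training", True)
        return self

    def eval(self):
        for m in self.modules():
            object.__setattr__(m, "training", False)
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array view of all parameters and buffers."""
        out = {}
        for name, p in self._params.items():
            out[name] = p.data
        for name, m in self._modules.items():
            for sub, arr in m.state_arrays().items():
                out[f"{name}.{sub}"] = arr
        for name in getattr(self, "_buffers", ()):
            out[name] = getattr(self, name)
        return out

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, zero_init: bool = False):
        super().__init__()
        if zero_init:
            w = np.zeros((in_features, out_features))
        else:
            w = _kaiming(rng, in_features, (in_features, out_features))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, padding: int | None = None,
                 zero_init: bool = False):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        if zero_init:
            w = np.zeros((out_ch, in_ch, kernel, kernel))
        else:
            w = _kaiming(rng, fan_in, (out_ch, in_ch, kernel, kernel))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)
        self.padding = kernel // 2 if padding is None else padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding)


class _BatchNorm(Module):
    """Shared batch-norm core; subclasses fix the reduction axes."""

    def __init__(self, num_features: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        object.__setattr__(self, "_buffers", ("running_mean", "running_var"))

    _axes: tuple[int, ...] = (0,)

    def _param_shape(self, x: Tensor):
        shape = [1] * x.ndim
        shape[1 if x.ndim == 4 else -1] = -1
        return tuple(shape)

    def forward(self, x: Tensor) -> Tensor:
        shp = self._param_shape(x)
        if self.training:
            mu = x.mean(axis=self._axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=self._axes, keepdims=True)
            self.running_mean += self.momentum * (mu.data.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (var.data.reshape(-1) - self.running_var)
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            mu = self.running_mean.reshape(shp)
            sd = np.sqrt(self.running_var + self.eps).reshape(shp)
            xhat = (x - Tensor(mu)) * Tensor(1.0 / sd)
        return xhat * self.gamma.reshape(shp) + self.beta.reshape(shp)


class BatchNorm1d(_BatchNorm):
    _axes = (0,)


class BatchNorm2d(_BatchNorm):
    _axes = (0, 2, 3)


class LayerNorm(Module):
    """Normalises over the last axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; active only in training mode.

    The mask stream is seeded at construction so a full training run is
    reproducible from the model seed.
    """

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0,1); got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class MultiheadSelfAttention(Module):
    """Standard scaled dot-product multi-head self-attention.

    Operates on (N, L, D) token batches. ``zero_out`` zeroes the output
    projection, making the enclosing residual block an exact identity.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 zero_out: bool = False):
        super().__init__()
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.dim, self.heads, self.dk = dim, heads, dim // heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng, zero_init=zero_out)

    def forward(self, x: Tensor) -> Tensor:
        n, l, d = x.shape
        qkv = self.qkv(x)                                  # (N, L, 3D)
        qkv = qkv.reshape(n, l, 3, self.heads, self.dk)
        qkv = qkv.transpose(2, 0, 3, 1, 4)                 # (3, N, H, L, dk)
        q, k, v = qkv[0], qkv[1], qkv[2]
        att = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.dk))
        att = _softmax_lastaxis(att)                       # (N, H, L, L)
        out = att @ v                                      # (N, H, L, dk)
        out = out.transpose(0, 2, 1, 3).reshape(n, l, d)
        return self.proj(out)


def _softmax_lastaxis(x: Tensor) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=-1, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=-1, keepdims=True)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Adam:
    """Adam optimiser with the standard bias-corrected moments."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
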