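"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps a float64 ndarray and records the operations that
produced it; calling :meth:`Tensor.backward` on a scalar accumulates
gradients into every tensor in the graph (gradients are kept on
intermediate nodes too, which saliency mapping relies on).

Only the operations required by the model family in this package are
implemented. All ops are deterministic; any randomness (dropout masks,
weight init) lives in the calling modules.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "max_pool2x2", "upsample2x",
           "softmax_cross_entropy"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    # -- graph plumbing ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bwd(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bwd(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def bwd(g):
            self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / other.data ** 2, other.data.shape))
        out._backward = bwd
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _prev=(self,))
        out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out = Tensor(np.matmul(self.data, other.data), _prev=(self, other))

        def bwd(g):
            a, b = self.data, other.data
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            self._accumulate(_unbroadcast(ga, a.shape))
            other._accumulate(_unbroadcast(gb, b.shape))
        out._backward = bwd
        return out

    __matmul__ = matmul

    # -- shape ops --------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _prev=(self,))
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], _prev=(self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)
        out._backward = bwd
        return out

    # -- reductions -------------------------------------------------------

    def sum(self, axis=None, keepdims=False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis=axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())
        out._backward = bwd
        return out

    def amax(self, axis, keepdims=False) -> "Tensor":
        """Max over `axis`; gradient flows to the (first) argmax only."""
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        mx = self.data.max(axis=axes, keepdims=True)
        out = Tensor(mx if keepdims else np.squeeze(mx, axis=axes),
                     _prev=(self,))

        def bwd(g):
            if not keepdims:
                g = np.expand_dims(g, axis=axes)
            mask = self.data == mx
            # split gradient among ties to keep it well-defined
            counts = mask.sum(axis=axes, keepdims=True)
            self._accumulate(np.broadcast_to(g, self.data.shape) * mask / counts)
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ---------------------------------------------------

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))
        out._backward = lambda g: self._accumulate(g * (self.data > 0))
        return out

    def sigmoid(self) -> "Tensor":
        from scipy.special import expit
        s = expit(self.data)
        out = Tensor(s, _prev=(self,))
        out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, _prev=(self,))
        out._backward = lambda g: self._accumulate(g * e)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sqrt(self) -> "Tensor":
        return self ** 0.5

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


# -- free functions -------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])
    out._backward = bwd
    return out


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(N,C,H,W) -> (N, C*k*k, Ho*Wo) patch matrix."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    sn, sc, sh, sw = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, shape=(n, c, k, k, ho, wo),
        strides=(sn, sc, sh, sw, sh * stride, sw * stride))
    return cols.reshape(n, c * k * k, ho * wo), ho, wo


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int):
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    xg = np.zeros((n, c, hp, wp))
    cols = cols.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            xg[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += cols[:, :, i, j]
    if pad:
        xg = xg[:, :, pad:-pad, pad:-pad]
    return xg


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation). x: (N,C,H,W), w: (Co,C,k,k)."""
    co, ci, k, _ = w.data.shape
    cols, ho, wo = _im2col(x.data, k, stride, padding)
    wmat = w.data.reshape(co, ci * k * k)
    out_data = np.matmul(wmat, cols)                 # (N, Co, Ho*Wo)
    if b is not None:
        out_data = out_data + b.data.reshape(1, co, 1)
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data.reshape(-1, co, ho, wo), _prev=prev)

    def bwd(g):
        gmat = g.reshape(g.shape[0], co, ho * wo)
        w._accumulate(np.einsum("nop,ncp->oc", gmat, cols).reshape(w.data.shape))
        if b is not None:
            b._accumulate(gmat.sum(axis=(0, 2)))
        gcols = np.matmul(wmat.T, gmat)
        x._accumulate(_col2im(gcols, x.data.shape, k, stride, padding))
    out._backward = bwd
    return out


def max_pool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2. H and W must be even."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2x2 needs even H, W; got {h}x{w}")
    blocks = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out_data = blocks.max(axis=(3, 5))
    mask = blocks == out_data[:, :, :, None, :, None]
    # break ties deterministically: keep first max in each block
    flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    first = np.cumsum(flat, axis=-1) == 1
    mask = (flat & first).reshape(n, c, h // 2, w // 2, 2, 2).transpose(
        0, 1, 2, 4, 3, 5)
    out = Tensor(out_data, _prev=(x,))

    def bwd(g):
        gb = mask * g[:, :, :, None, :, None]
        x._accumulate(gb.reshape(n, c, h, w))
    out._backward = bwd
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling of (N,C,H,W)."""
    n, c, h, w = x.data.shape
    out = Tensor(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3), _prev=(x,))

    def bwd(g):
        x._accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))
    out._backward = bwd
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy over a batch. logits: (N,K); labels: (N,) ints."""
    labels = np.asarray(labels, dtype=np.int64)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.data.shape[0]
    loss = -np.log(probs[np.arange(n), labels] + 1e-300).mean()
    out = Tensor(loss, _prev=(logits,))

    def bwd(g):
        grad = probs.copy()
        grad[np.arange(n), labels] -= 1.0
        logits._accumulate(g * grad / n)
    out._backward = bwd
    return out
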