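"""Compact reverse-mode automatic differentiation on numpy arrays, plus AdamW.

Float64 throughout; single-threaded and fully deterministic given a seed,
which is the package's testing contract for model training.  The op set is
exactly what the curvature-biased transformer and the GCN baseline need:
broadcasting arithmetic, matmul, relu/exp/log/pow, reductions, indexing
(gather with scatter-add backward), concatenation, layer norm, and a masked
softmax.  Not a general deep-learning framework.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "layer_norm", "masked_softmax",
           "logsumexp", "absolute", "AdamW"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape` from `shape`."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    for _ in range(extra):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple = ()

    # -- graph plumbing --------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _acc(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        # iterative topological order over the op graph
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = _op(np.add(self.data, other.data), (self, other))
        def bwd(g):
            self._acc(_unbroadcast(g, self.data.shape))
            other._acc(_unbroadcast(g, other.data.shape))
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _op(-self.data, (self,))
        out._backward = lambda g: self._acc(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = _op(self.data * other.data, (self, other))
        def bwd(g):
            self._acc(_unbroadcast(g * other.data, self.data.shape))
            other._acc(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = _op(self.data ** exponent, (self,))
        out._backward = lambda g: self._acc(g * exponent * self.data ** (exponent - 1.0))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        if self.data.ndim != 2 or other.data.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")
        out = _op(self.data @ other.data, (self, other))
        def bwd(g):
            self._acc(g @ other.data.T)
            other._acc(self.data.T @ g)
        out._backward = bwd
        return out

    @property
    def T(self) -> "Tensor":
        out = _op(self.data.T, (self,))
        out._backward = lambda g: self._acc(g.T)
        return out

    def reshape(self, *shape) -> "Tensor":
        out = _op(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self._acc(g.reshape(self.data.shape))
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = _op(self.data[idx], (self,))
        def bwd(g):
            buf = np.zeros_like(self.data)
            np.add.at(buf, idx, g)
            self._acc(buf)
        out._backward = bwd
        return out

    # -- elementwise nonlinearities -------------------------------------
    def relu(self) -> "Tensor":
        out = _op(np.maximum(self.data, 0.0), (self,))
        out._backward = lambda g: self._acc(g * (self.data > 0))
        return out

    def exp(self) -> "Tensor":
        out = _op(np.exp(self.data), (self,))
        out._backward = lambda g: self._acc(g * out.data)
        return out

    def log(self) -> "Tensor":
        out = _op(np.log(self.data), (self,))
        out._backward = lambda g: self._acc(g / self.data)
        return out

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False) -> "Tensor":
        out = _op(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        def bwd(g):
            if axis is None:
                self._acc(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._acc(np.broadcast_to(gg, self.data.shape).copy())
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _op(data: np.ndarray, prev: tuple) -> Tensor:
    out = Tensor(data)
    out._prev = tuple(p for p in prev if isinstance(p, Tensor))
    out.requires_grad = any(p.requires_grad or p._prev or p._backward for p in out._prev)
    return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _op(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._acc(g[tuple(sl)])
    out._backward = bwd
    return out


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize the last axis to zero mean / unit variance, then scale and shift."""
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered * (var + eps) ** -0.5 * gain + bias


def masked_softmax(x: Tensor, mask: np.ndarray | None = None) -> Tensor:
    """Row-wise softmax over the last axis; masked (0) keys receive zero weight.

    The shift constant is the row max of the raw data (treated as a constant;
    softmax is shift-invariant so the gradient is unchanged).
    """
    if mask is not None:
        shift = np.where(mask, x.data, -np.inf).max(axis=-1, keepdims=True)
    else:
        shift = x.data.max(axis=-1, keepdims=True)
    e = (x - Tensor(shift)).exp()
    if mask is not None:
        e = e * Tensor(mask.astype(np.float64))
    return e * e.sum(axis=-1, keepdims=True) ** -1.0


def logsumexp(x: Tensor, axis: int = -1) -> Tensor:
    shift = x.data.max(axis=axis, keepdims=True)
    return (x - Tensor(shift)).exp().sum(axis=axis, keepdims=True).log() + Tensor(shift)


def absolute(x: Tensor) -> Tensor:
    """|x| as relu(x) + relu(-x) (subgradient 0 at 0)."""
    return x.relu() + (-x).relu()


class AdamW(object):
    """AdamW with decoupled weight decay and an optional learning-rate floor.

    Defaults mirror the training setup used throughout the package: eps 1e-8,
    betas (0.99, 0.999); the floor only matters when a decaying schedule is
    supplied externally via ``set_lr``.
    """

    def __init__(self, params: list[Tensor], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.99, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0, lr_min: float = 1e-9):
        self.params = list(params)
        self.lr = float(lr)
        self.lr_min = float(lr_min)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def set_lr(self, lr: float):
        self.lr = max(float(lr), self.lr_min)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
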