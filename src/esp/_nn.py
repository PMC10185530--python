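"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the package's neural components need:
matrix products, broadcast addition, elementwise nonlinearities, softmax,
axis reductions and concatenation. Gradients flow through a dynamically
built tape; :func:`backward` runs the tape in reverse topological order.
An Adam optimizer with fixed, documented defaults is included.

This is deliberately a small engine, not a general framework: the molecule
and enzyme encoders in this package are desk-scale models (hidden sizes of
tens to low hundreds), where plain numpy matmuls are fast enough.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "parameter", "matmul", "concat", "backward", "Adam"]


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "parents", "backward_fn", "requires_grad")

    def __init__(self, data, parents=(), backward_fn=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.parents = parents
        self.backward_fn = backward_fn
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    # operator sugar -------------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), _as_tensor(-1.0)))

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def tensor(data) -> Tensor:
    """Constant (non-trainable) tensor."""
    return Tensor(data)


def parameter(data) -> Tensor:
    """Trainable tensor."""
    return Tensor(np.array(data, dtype=np.float64, copy=True), requires_grad=True)


def _accumulate(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    g = _unbroadcast(g, t.data.shape)
    t.grad = g if t.grad is None else t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


# ---------------------------------------------------------------------------
# primitive ops


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, (a, b))
    out.backward_fn = lambda g: (_accumulate(a, g), _accumulate(b, g))
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, (a, b))
    out.backward_fn = lambda g: (
        _accumulate(a, g * b.data),
        _accumulate(b, g * a.data),
    )
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, (a, b))

    def bw(g):
        if a.data.ndim == 2 and b.data.ndim == 2:
            _accumulate(a, g @ b.data.T)
            _accumulate(b, a.data.T @ g)
        elif a.data.ndim == 1 and b.data.ndim == 2:
            _accumulate(a, g @ b.data.T)
            _accumulate(b, np.outer(a.data, g))
        elif a.data.ndim == 2 and b.data.ndim == 1:
            _accumulate(a, np.outer(g, b.data))
            _accumulate(b, a.data.T @ g)
        else:  # vector dot product
            _accumulate(a, g * b.data)
            _accumulate(b, g * a.data)

    out.backward_fn = bw
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(a.data * mask, (a,))
    out.backward_fn = lambda g: _accumulate(a, g * mask)
    return out


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))
    out = Tensor(s, (a,))
    out.backward_fn = lambda g: _accumulate(a, g * s * (1 - s))
    return out


def tanh(a: Tensor) -> Tensor:
    t = np.tanh(a.data)
    out = Tensor(t, (a,))
    out.backward_fn = lambda g: _accumulate(a, g * (1 - t * t))
    return out


def log(a: Tensor, eps: float = 1e-12) -> Tensor:
    out = Tensor(np.log(a.data + eps), (a,))
    out.backward_fn = lambda g: _accumulate(a, g / (a.data + eps))
    return out


def square(a: Tensor) -> Tensor:
    out = Tensor(a.data ** 2, (a,))
    out.backward_fn = lambda g: _accumulate(a, 2.0 * g * a.data)
    return out


def mean(a: Tensor, axis=None) -> Tensor:
    out = Tensor(a.data.mean(axis=axis), (a,))
    n = a.data.size if axis is None else a.data.shape[axis]

    def bw(g):
        g = np.asarray(g)
        if axis is not None:
            g = np.expand_dims(g, axis)
        _accumulate(a, np.broadcast_to(g, a.data.shape) / n)

    out.backward_fn = bw
    return out


def total(a: Tensor, axis=None) -> Tensor:
    out = Tensor(a.data.sum(axis=axis), (a,))

    def bw(g):
        g = np.asarray(g)
        if axis is not None:
            g = np.expand_dims(g, axis)
        _accumulate(a, np.broadcast_to(g, a.data.shape))

    out.backward_fn = bw
    return out


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, (a,))

    def bw(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        _accumulate(a, s * (g - dot))

    out.backward_fn = bw
    return out


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accumulate(t, piece)

    out.backward_fn = bw
    return out


def stack_scalars(tensors: list[Tensor]) -> Tensor:
    """Stack 0-d tensors into a vector."""
    out = Tensor(np.array([t.data for t in tensors]), tuple(tensors))

    def bw(g):
        for t, gi in zip(tensors, g):
            _accumulate(t, np.asarray(gi))

    out.backward_fn = bw
    return out


def rows(a: Tensor, index) -> Tensor:
    """Gather rows; gradient scatter-adds back."""
    idx = np.asarray(index)
    out = Tensor(a.data[idx], (a,))

    def bw(g):
        if a.requires_grad:
            ga = np.zeros_like(a.data)
            np.add.at(ga, idx, g)
            _accumulate(a, ga)

    out.backward_fn = bw
    return out


def backward(loss: Tensor) -> None:
    """Reverse-mode sweep from a scalar loss."""
    order: list[Tensor] = []
    seen: set[int] = set()
    stack = [(loss, False)]
    while stack:  # iterative DFS: graphs can exceed the recursion limit
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            stack.append((p, False))
    loss.grad = np.ones_like(loss.data)
    for node in reversed(order):
        if node.backward_fn is not None:
            node.backward_fn(node.grad)


class Adam:
    """Adaptive-moment optimizer (lr 1e-3, betas 0.9/0.999, eps 1e-8)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    """Glorot-uniform initialization."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def bce_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits."""
    y = Tensor(np.asarray(labels, dtype=np.float64))
    p = sigmoid(logits)
    one = Tensor(np.ones_like(y.data))
    losses = mul(y, log(p)) + mul(one - y, log(one - p))
    return mul(mean(losses), Tensor(-1.0))


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    t = Tensor(np.asarray(target, dtype=np.float64))
    return mean(square(pred - t))
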