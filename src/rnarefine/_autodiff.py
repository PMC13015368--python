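"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the equivariant denoiser needs: dense
affine maps, elementwise arithmetic with broadcasting, SiLU/tanh
nonlinearities, concatenation, row gathering and segment summation (the
two primitives of message passing), and reductions. Gradients are checked
against finite differences in the test suite.

This is deliberately tiny: tensors record their parents and a closure
that routes the incoming gradient; ``backward`` runs a topological sort
and accumulates into ``grad``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "concat", "gather", "segment_sum", "silu", "tanh", "power",
    "scatter_rows", "Adam",
]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph machinery ---------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # -- ops ---------------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)

        def back(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))
        return Tensor(self.data + other.data, parents=(self, other), backward=back)

    __radd__ = __add__

    def __sub__(self, other):
        other = _as_tensor(other)

        def back(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(-g, other.data.shape))
        return Tensor(self.data - other.data, parents=(self, other), backward=back)

    def __mul__(self, other):
        other = _as_tensor(other)

        def back(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))
        return Tensor(self.data * other.data, parents=(self, other), backward=back)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = _as_tensor(other)

        def back(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)
        return Tensor(self.data @ other.data, parents=(self, other), backward=back)

    def sum(self):
        def back(g):
            self._accumulate(np.full_like(self.data, float(g)))
        return Tensor(self.data.sum(), parents=(self,), backward=back)

    def sum_axis(self, axis: int, keepdims: bool = True):
        def back(g):
            self._accumulate(np.broadcast_to(
                g if keepdims else np.expand_dims(g, axis), self.data.shape).copy())
        return Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                      parents=(self,), backward=back)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    g = np.asarray(g)
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])
    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  parents=tuple(tensors), backward=back)


def scatter_rows(out: np.ndarray, index: np.ndarray, vals: np.ndarray) -> np.ndarray:
    """out[index] += vals, using the fast reduceat path when index is sorted."""
    if len(index) and np.all(index[1:] >= index[:-1]):
        uniq, starts = np.unique(index, return_index=True)
        out[uniq] += np.add.reduceat(vals, starts, axis=0)
    else:
        np.add.at(out, index, vals)
    return out


def gather(t: Tensor, index: np.ndarray) -> Tensor:
    """Row selection t[index]; backward scatter-adds into the source."""
    index = np.asarray(index, dtype=int)

    def back(g):
        t._accumulate(scatter_rows(np.zeros_like(t.data), index, g))
    return Tensor(t.data[index], parents=(t,), backward=back)


def segment_sum(t: Tensor, index: np.ndarray, n: int) -> Tensor:
    """Sum rows of ``t`` into ``n`` buckets given per-row bucket ids."""
    index = np.asarray(index, dtype=int)
    out = scatter_rows(np.zeros((n,) + t.data.shape[1:], dtype=t.data.dtype),
                       index, t.data)

    def back(g):
        t._accumulate(g[index])
    return Tensor(out, parents=(t,), backward=back)


def silu(t: Tensor) -> Tensor:
    from scipy.special import expit

    sig = expit(t.data)
    val = t.data * sig

    def back(g):
        t._accumulate(g * (sig * (1.0 + t.data * (1.0 - sig))))
    return Tensor(val, parents=(t,), backward=back)


def power(t: Tensor, p: float) -> Tensor:
    """Elementwise t**p (t must be positive where p is fractional)."""
    val = t.data ** p

    def back(g):
        t._accumulate(g * (p * t.data ** (p - 1)))
    return Tensor(val, parents=(t,), backward=back)


def tanh(t: Tensor) -> Tensor:
    val = np.tanh(t.data)

    def back(g):
        t._accumulate(g * (1.0 - val ** 2))
    return Tensor(val, parents=(t,), backward=back)


class Adam:
    """Adam over a named collection of parameter tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()
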