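"""Minimal reverse-mode automatic differentiation on numpy arrays.

Both neural networks in this package (the graph network scoring cell
assignments and the fully connected lineage classifier) are small enough
that a dependency-free tensor engine is preferable to a deep-learning
framework: training runs single-threaded on a laptop CPU in seconds to
minutes, and bit-reproducibility under a fixed seed is trivial to
guarantee because every operation is a deterministic numpy call.

The engine supports exactly the primitives the models need: broadcasted
arithmetic, matmul, ReLU/ELU, exp/log/sqrt, axis reductions, row gather,
and segment (scatter-add) sums for graph message aggregation. Gradients
flow through a dynamically recorded tape; `backward` performs a
topological sweep.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam"]


def _scatter_add(idx: np.ndarray, data: np.ndarray, n: int) -> np.ndarray:
    """Row scatter-add via bincount (much faster than np.add.at)."""
    if data.ndim == 1:
        return np.bincount(idx, weights=data,
                           minlength=n).astype(data.dtype, copy=False)
    h = data.shape[1]
    flat_idx = (idx[:, None] * h + np.arange(h)).ravel()
    return np.bincount(flat_idx, weights=data.ravel(),
                       minlength=n * h).reshape(n, h).astype(data.dtype,
                                                             copy=False)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float64)
        self.data = arr        # float dtype preserved (float32 models work)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def param(data) -> "Tensor":
        return Tensor(np.array(data), requires_grad=True)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        if isinstance(other, (int, float)):    # scalar fast path, dtype-safe
            out = Tensor(self.data + other, self.requires_grad, (self,))
            out._backward = lambda g: (g,)
            return out
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd(g):
            return (_unbroadcast(g, self.data.shape),
                    _unbroadcast(g, other.data.shape))
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            out = Tensor(self.data * other, self.requires_grad, (self,))
            out._backward = lambda g: (g * other,)
            return out
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd(g):
            return (_unbroadcast(g * other.data, self.data.shape),
                    _unbroadcast(g * self.data, other.data.shape))
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = Tensor._lift(other)
        out = Tensor(self.data / other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd(g):
            return (_unbroadcast(g / other.data, self.data.shape),
                    _unbroadcast(-g * self.data / other.data ** 2,
                                 other.data.shape))
        out._backward = bwd
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd(g):
            return (g @ other.data.T, self.data.T @ g)
        out._backward = bwd
        return out

    __matmul__ = matmul

    # -- nonlinearities -------------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, (self,))
        out._backward = lambda g: (g * mask,)
        return out

    def elu(self, alpha: float = 1.0) -> "Tensor":
        pos = self.data > 0
        neg = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        val = np.where(pos, self.data, neg)
        out = Tensor(val, self.requires_grad, (self,))
        out._backward = lambda g: (g * np.where(pos, 1.0, neg + alpha),)
        return out

    def exp(self) -> "Tensor":
        val = np.exp(self.data)
        out = Tensor(val, self.requires_grad, (self,))
        out._backward = lambda g: (g * val,)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        out._backward = lambda g: (g / self.data,)
        return out

    def sqrt(self) -> "Tensor":
        val = np.sqrt(self.data)
        out = Tensor(val, self.requires_grad, (self,))
        out._backward = lambda g: (g / (2.0 * val),)
        return out

    # -- reductions / reshaping ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def gather_rows(self, idx: np.ndarray) -> "Tensor":
        idx = np.asarray(idx, dtype=np.intp)
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def bwd(g):
            return (_scatter_add(idx, g, self.data.shape[0]),)
        out._backward = bwd
        return out

    def segment_sum(self, idx: np.ndarray, n_segments: int) -> "Tensor":
        """Scatter-add rows into `n_segments` buckets given per-row bucket ids."""
        idx = np.asarray(idx, dtype=np.intp)
        acc = _scatter_add(idx, self.data, n_segments)
        out = Tensor(acc, self.requires_grad, (self,))
        out._backward = lambda g: (g[idx],)
        return out

    def spmm(self, S, ST) -> "Tensor":
        """Sparse @ dense: out = S @ self, with S.T (``ST``) precomputed for
        the backward pass. Used for graph segment sums (rows of ``self``
        scatter-added into segments): S is the (n_segments x n_rows)
        incidence matrix."""
        out = Tensor(S @ self.data, self.requires_grad, (self,))
        out._backward = lambda g: (ST @ g,)
        return out

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- backward sweep -------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if id(node) in seen:
                continue
            if expanded:
                seen.add(id(node))
                order.append(node)
            else:
                stack.append((node, True))
                for p in node._parents:
                    if id(p) not in seen:
                        stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


class Adam:
    """Adam optimizer over a flat list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
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
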