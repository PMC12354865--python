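"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains a small transformer on CPU; rather than pulling in a
deep-learning framework, this module provides exactly the tensor operations
that model needs (broadcasted arithmetic, batched matmul, softmax, layer
normalization, dropout) with gradients accumulated by reverse-mode
backpropagation. Everything is float64, which keeps finite-difference
gradient checks tight.

Only `Tensor`, `Adam` and the `concat` helper are public API; layers live in
`wsisurv.model`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast so it matches `shape`."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self.grad = None
        self._parents = _parents
        self._backward = _backward

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autograd engine ------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.grad is None:
                t.grad = g.copy()
            else:
                t.grad = t.grad + g
            if t._backward is None:
                continue
            for parent, pg in t._backward(g):
                if not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg
        # intermediate grads were stored on t.grad too; that is harmless and
        # occasionally useful (e.g. gradients w.r.t. an input tensor).

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            return ((self, _unbroadcast(g, self.data.shape)),
                    (other, _unbroadcast(g, other.data.shape)))

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            return ((self, -g),)

        return Tensor(-self.data, _parents=(self,), _backward=bwd)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data * other.data

        def bwd(g):
            return ((self, _unbroadcast(g * other.data, self.data.shape)),
                    (other, _unbroadcast(g * self.data, other.data.shape)))

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * Tensor.as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        out_data = self.data ** p

        def bwd(g):
            return ((self, g * p * self.data ** (p - 1.0)),)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data @ other.data

        def bwd(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:
                ga, gb = g * b, g * a
            elif b.ndim == 1:
                ga = np.multiply.outer(g, b) if a.ndim > 1 else g * b
                gb = np.swapaxes(a, -1, -2) @ g if a.ndim > 1 else g * a
                if a.ndim > 2:
                    gb = gb.reshape(-1, gb.shape[-1]).sum(0)
            elif a.ndim == 1:
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.multiply.outer(a, g)
            else:
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.swapaxes(a, -1, -2) @ g
            return ((self, _unbroadcast(np.asarray(ga), a.shape)),
                    (other, _unbroadcast(np.asarray(gb), b.shape)))

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            return ((self, g * out_data),)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def log(self):
        def bwd(g):
            return ((self, g / self.data),)

        return Tensor(np.log(self.data), _parents=(self,), _backward=bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g):
            return ((self, g * (1.0 - out_data ** 2)),)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            return ((self, g * mask),)

        return Tensor(self.data * mask, _parents=(self,), _backward=bwd)

    def sqrt(self):
        return self ** 0.5

    # -- reductions & shape ---------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return ((self, np.broadcast_to(g, self.data.shape).copy()),)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bwd(g):
            return ((self, g.reshape(old)),)

        return Tensor(self.data.reshape(shape), _parents=(self,), _backward=bwd)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)

        def bwd(g):
            return ((self, g.transpose(inv)),)

        return Tensor(self.data.transpose(axes), _parents=(self,), _backward=bwd)

    def swap_last(self):
        """Transpose the last two axes (for batched attention)."""
        nd = self.data.ndim
        axes = tuple(range(nd - 2)) + (nd - 1, nd - 2)
        return self.transpose(*axes)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return ((self, full),)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    # -- composite ops --------------------------------------------------------
    def softmax(self, axis: int = -1):
        shifted = self - np.max(self.data, axis=axis, keepdims=True)
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def logsumexp(self, axis=None, keepdims: bool = False):
        m = np.max(self.data, axis=axis, keepdims=True)
        e = (self - m).exp()
        out = e.sum(axis=axis, keepdims=True).log() + m
        if not keepdims and axis is not None:
            out = out.reshape(tuple(s for i, s in enumerate(self.data.shape) if i != (axis % self.data.ndim)))
        elif not keepdims and axis is None:
            out = out.reshape(())
        return out

    def dropout(self, p: float, rng: np.random.Generator):
        """Inverted dropout; call only in training mode."""
        if p <= 0.0:
            return self
        mask = (rng.random(self.data.shape) >= p) / (1.0 - p)
        return self * Tensor(mask)


def concat(tensors, axis: int = 0) -> Tensor:
    """Concatenate tensors along an axis with gradient routing."""
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        pairs = []
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            pairs.append((t, g[tuple(sl)]))
        return tuple(pairs)

    return Tensor(out_data, _parents=tuple(tensors), _backward=bwd)


class Adam:
    """Adam optimizer over a dict of named parameter Tensors."""

    def __init__(self, params: dict, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
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
            g = p.grad
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
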