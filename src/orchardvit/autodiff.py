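"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the tape in reverse topological order and
accumulates gradients.  Only the operations the transformer and the loss
family need are implemented: broadcast-aware arithmetic, batched matmul,
exp/log/tanh/sqrt, power with a constant exponent, softmax over the last
axis, reductions, reshapes, transposes, slicing and concatenation.

Broadcasting is handled by summing gradients over broadcast axes on the way
back (:func:`_unbroadcast`), so parameters of any shape compose freely with
batched activations.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "exp", "log", "tanh", "sqrt", "clip", "softmax", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray with a gradient tape.

    Parameters
    ----------
    data : array-like
        Values, stored as ``float64``.
    requires_grad : bool
        Whether gradients should be accumulated into ``.grad``.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = Tensor._lift(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, exponent: float):
        """Elementwise power with a *constant* exponent."""
        c = float(exponent)
        out_data = self.data**c

        def backward(g):
            return (g * c * self.data ** (c - 1.0),)

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        """Batched matrix product; both operands must be at least 2-D."""
        other = Tensor._lift(other)
        if self.ndim < 2 or other.ndim < 2:
            raise ValueError("matmul requires operands with ndim >= 2")
        out_data = self.data @ other.data

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        return self._make(out_data, (self, other), backward)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        orig = self.shape
        out_data = self.data.reshape(*shape)
        return self._make(out_data, (self,), lambda g: (g.reshape(orig),))

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out_data = self.data.transpose(*axes)
        return self._make(out_data, (self,), lambda g: (g.transpose(*inv),))

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return self._make(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- backward pass --------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every tape ancestor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() on a non-scalar requires an explicit gradient")
            grad = np.ones_like(self.data)

        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: deep graphs must not hit the recursion limit
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg
            if node is self or not node._parents:
                node.grad = g if node.grad is None else node.grad + g


# -- elementwise functions (dispatch on Tensor vs ndarray) --------------------


def _dispatch(x, np_fn, tensor_fn):
    if isinstance(x, Tensor):
        return tensor_fn(x)
    return np_fn(np.asarray(x, dtype=np.float64))


def exp(x):
    def t(x: Tensor):
        out_data = np.exp(x.data)
        return x._make(out_data, (x,), lambda g: (g * out_data,))

    return _dispatch(x, np.exp, t)


def log(x):
    def t(x: Tensor):
        return x._make(np.log(x.data), (x,), lambda g: (g / x.data,))

    return _dispatch(x, np.log, t)


def tanh(x):
    def t(x: Tensor):
        out_data = np.tanh(x.data)
        return x._make(out_data, (x,), lambda g: (g * (1.0 - out_data**2),))

    return _dispatch(x, np.tanh, t)


def sqrt(x):
    def t(x: Tensor):
        out_data = np.sqrt(x.data)
        return x._make(out_data, (x,), lambda g: (g * 0.5 / out_data,))

    return _dispatch(x, np.sqrt, t)


def clip(x, lo: float, hi: float):
    """Clamp to [lo, hi]; the gradient is passed through only inside the range."""

    def t(x: Tensor):
        out_data = np.clip(x.data, lo, hi)
        mask = (x.data >= lo) & (x.data <= hi)

        def backward(g):
            return (g * mask,)

        return x._make(out_data, (x,), backward)

    return _dispatch(x, lambda a: np.clip(a, lo, hi), t)


def softmax(x, axis: int = -1):
    """Numerically stable softmax along ``axis``."""

    def np_softmax(a):
        a = a - a.max(axis=axis, keepdims=True)
        e = np.exp(a)
        return e / e.sum(axis=axis, keepdims=True)

    def t(x: Tensor):
        out_data = np_softmax(x.data)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            return (out_data * (g - dot),)

        return x._make(out_data, (x,), backward)

    return _dispatch(x, np_softmax, t)


def concat(tensors: list, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out
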