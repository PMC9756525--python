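"""Reverse-mode automatic differentiation over NumPy arrays.

This is the package's compute engine: a small define-by-run tape of
:class:`Tensor` nodes, each holding a ``numpy.ndarray`` and a closure that
propagates the upstream gradient to its parents.  Only the operations the
interaction model needs are implemented (dense algebra, 1-D convolution via
unfolding, gather/segment reductions for graph message passing, and the
usual pointwise nonlinearities).  Gradients are exact analytic expressions;
the test suite checks them against central finite differences.

All arrays are float64.  The engine is single-threaded apart from whatever
BLAS backs ``numpy.matmul``.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "gather_rows",
    "segment_sum",
    "unfold1d",
    "softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the autodiff graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # -- bookkeeping -------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from a scalar node through the whole tape."""
        if self.data.size != 1:
            raise ValueError("backward() is only defined for scalar tensors")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep graphs would blow the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self._accum(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data + other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, requires_grad=self.requires_grad,
                     parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        out._backward = backward
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data * other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data / other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                          other.data.shape))

        out._backward = backward
        return out

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) / self

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data @ other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = backward
        return out

    @property
    def T(self) -> "Tensor":
        out = Tensor(self.data.T, requires_grad=self.requires_grad,
                     parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g.T)

        out._backward = backward
        return out

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape),
                     requires_grad=self.requires_grad, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = backward
        return out

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     requires_grad=self.requires_grad, parents=(self,))

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.full_like(self.data, float(g)))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        mx = self.data.max(axis=axis, keepdims=True)
        out_data = mx if keepdims else np.squeeze(mx, axis=axis)
        out = Tensor(out_data, requires_grad=self.requires_grad,
                     parents=(self,))

        def backward(g):
            if not self.requires_grad:
                return
            mask = (self.data == mx)
            # split gradient evenly among ties
            mask = mask / mask.sum(axis=axis, keepdims=True)
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accum(mask * gg)

        out._backward = backward
        return out

    # -- pointwise nonlinearities -----------------------------------------

    def exp(self) -> "Tensor":
        y = np.exp(self.data)
        out = Tensor(y, requires_grad=self.requires_grad, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * y)

        out._backward = backward
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), requires_grad=self.requires_grad,
                     parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = backward
        return out

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = Tensor(y, requires_grad=self.requires_grad, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - y * y))

        out._backward = backward
        return out

    def sigmoid(self) -> "Tensor":
        # numerically stable logistic
        y = np.where(self.data >= 0,
                     1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500))),
                     np.exp(np.clip(self.data, -500, 500))
                     / (1.0 + np.exp(np.clip(self.data, -500, 500))))
        out = Tensor(y, requires_grad=self.requires_grad, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * y * (1.0 - y))

        out._backward = backward
        return out

    def leaky_relu(self, negative_slope: float = 0.01) -> "Tensor":
        slope_mask = np.where(self.data > 0, 1.0, negative_slope)
        out = Tensor(self.data * slope_mask,
                     requires_grad=self.requires_grad, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * slope_mask)

        out._backward = backward
        return out

    def clip(self, lo: float, hi: float) -> "Tensor":
        out = Tensor(np.clip(self.data, lo, hi),
                     requires_grad=self.requires_grad, parents=(self,))

        def backward(g):
            if self.requires_grad:
                inside = (self.data >= lo) & (self.data <= hi)
                self._accum(g * inside)

        out._backward = backward
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 requires_grad=any(t.requires_grad for t in tensors),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    out._backward = backward
    return out


def gather_rows(x: Tensor, indices: np.ndarray) -> Tensor:
    """Select rows ``x[indices]``; gradient scatter-adds back."""
    indices = np.asarray(indices, dtype=np.intp)
    out = Tensor(x.data[indices], requires_grad=x.requires_grad, parents=(x,))

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            np.add.at(gx, indices, g)
            x._accum(gx)

    out._backward = backward
    return out


def segment_sum(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of `x` into `num_segments` buckets given per-row ids."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    y = np.zeros((num_segments,) + x.data.shape[1:], dtype=np.float64)
    np.add.at(y, segment_ids, x.data)
    out = Tensor(y, requires_grad=x.requires_grad, parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accum(g[segment_ids])

    out._backward = backward
    return out


def unfold1d(x: Tensor, kernel_size: int) -> Tensor:
    """Zero-padded sliding windows along axis 0.

    Maps an (L, C) tensor to (L, kernel_size * C), row i holding the
    concatenated rows i-k//2 … i+k//2 (zeros outside the sequence).  This is
    the im2col step of a same-length 1-D convolution: a convolution is then
    a single matmul with a (kernel_size*C, D) weight.
    """
    if kernel_size % 2 != 1:
        raise ValueError("kernel_size must be odd for same-length output")
    L, C = x.data.shape
    half = kernel_size // 2
    padded = np.zeros((L + 2 * half, C), dtype=np.float64)
    padded[half:half + L] = x.data
    cols = np.empty((L, kernel_size, C), dtype=np.float64)
    for o in range(kernel_size):
        cols[:, o, :] = padded[o:o + L]
    out = Tensor(cols.reshape(L, kernel_size * C),
                 requires_grad=x.requires_grad, parents=(x,))

    def backward(g):
        if not x.requires_grad:
            return
        g3 = g.reshape(L, kernel_size, C)
        gpad = np.zeros((L + 2 * half, C), dtype=np.float64)
        for o in range(kernel_size):
            gpad[o:o + L] += g3[:, o, :]
        x._accum(gpad[half:half + L])

    out._backward = backward
    return out


def unfold1d_data(x: np.ndarray, kernel_size: int) -> np.ndarray:
    """Plain-array version of :func:`unfold1d` for weight-independent caching."""
    return unfold1d(Tensor(x), kernel_size).data


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax built from primitive ops."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant shift
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)
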