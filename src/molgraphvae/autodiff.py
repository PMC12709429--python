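"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small tape-based engine: a :class:`Tensor` wraps an
ndarray, records its parents and a backward closure, and ``backward()``
runs the chain rule over a topological sort.  Float64 throughout — the
networks built on this are small, and exactness simplifies the
invariance and gradient tests.

Supported primitives are exactly those the graph-attention encoder and
transformer decoder need: broadcast arithmetic, matmul, exp/log/tanh,
(leaky) ReLU, reductions, reshape/transpose/concat, integer gather and
segment-sum scatter.  Softmax and layer normalization are composed from
these in :mod:`molgraphvae.nn`.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size-1 in the original
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _from_op(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._from_op(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            return (g * exponent * self.data ** (exponent - 1),)

        return Tensor._from_op(out_data, (self,), backward)

    def __matmul__(self, other):
        other = _as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1:
                a = a[None, :]
            if b.ndim == 1:
                b = b[:, None]
            ga = g @ np.swapaxes(b, -1, -2) if g.ndim > 1 else np.outer(g, b).reshape(self.shape)
            gb = np.swapaxes(a, -1, -2) @ g if g.ndim > 1 else np.outer(a, g).reshape(other.shape)
            return (_unbroadcast(ga.reshape(ga.shape), self.shape), _unbroadcast(gb, other.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    # -- elementwise ---------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._from_op(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._from_op(np.log(self.data), (self,), lambda g: (g / self.data,))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._from_op(out_data, (self,), lambda g: (g * (1 - out_data**2),))

    def relu(self):
        mask = self.data > 0
        return Tensor._from_op(self.data * mask, (self,), lambda g: (g * mask,))

    def leaky_relu(self, alpha: float = 0.2):
        slope = np.where(self.data > 0, 1.0, alpha)
        return Tensor._from_op(self.data * slope, (self,), lambda g: (g * slope,))

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ---------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor._from_op(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(self.shape),)
        )

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._from_op(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def __getitem__(self, index):
        out_data = self.data[index]

        def backward(g):
            gx = np.zeros_like(self.data)
            np.add.at(gx, index, g)
            return (gx,)

        return Tensor._from_op(out_data, (self,), backward)

    # -- autodiff driver -----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar output")
            grad = np.ones_like(self.data)
        topo, visited = [], set()

        def visit(t: "Tensor"):
            if id(t) in visited or not t.requires_grad:
                return
            visited.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is not None:
                for parent, pg in zip(t._parents, t._backward(g)):
                    if not parent.requires_grad or pg is None:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg
            else:  # leaf
                t.grad = g if t.grad is None else t.grad + g
        # non-leaf tensors with no _backward are leaves handled above; make
        # sure the root itself keeps its grad when it is a leaf
        if self._backward is None and self.requires_grad and self.grad is None:
            self.grad = np.asarray(grad, dtype=np.float64)


# --------------------------------------------------------------------------
# free functions


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        return tuple(
            np.take(g, np.arange(offsets[i], offsets[i + 1]), axis=axis)
            for i in range(len(tensors))
        )

    return Tensor._from_op(out_data, tensors, backward)


def segment_sum(x: Tensor, index: np.ndarray, num_segments: int) -> Tensor:
    """Scatter-add rows of ``x`` into ``num_segments`` buckets.

    ``out[s] = sum over rows i with index[i] == s of x[i]``; the backbone
    of global-add-pool readout and of attention normalization over the
    in-edges of each node.
    """
    index = np.asarray(index, dtype=np.int64)
    out_data = np.zeros((num_segments,) + x.shape[1:], dtype=np.float64)
    np.add.at(out_data, index, x.data)
    return Tensor._from_op(out_data, (x,), lambda g: (g[index],))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - np.max(x.data, axis=axis, keepdims=True)  # detached max
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - np.max(x.data, axis=axis, keepdims=True)
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def segment_softmax(scores: Tensor, index: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of ``scores`` within each segment of ``index``."""
    index = np.asarray(index, dtype=np.int64)
    # detached per-segment max for numerical stability
    seg_max = np.full((num_segments,) + scores.shape[1:], -np.inf)
    np.maximum.at(seg_max, index, scores.data)
    seg_max[~np.isfinite(seg_max)] = 0.0  # empty segments
    e = (scores - seg_max[index]).exp()
    denom = segment_sum(e, index, num_segments)
    return e / denom[index]
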