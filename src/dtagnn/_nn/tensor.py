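"""Reverse-mode automatic differentiation over numpy arrays.

This is a deliberately small engine: a :class:`Tensor` wraps a float64
``numpy.ndarray`` together with the closure needed to backpropagate through
the operation that produced it.  It supports exactly the operations the
affinity model needs — dense linear algebra, pointwise nonlinearities,
gather/scatter by integer index (for sparse graph message passing and
embedding lookup), segment reductions, and sliding-window unfolding for 1D
convolution.  Gradients are accumulated by a topological-order sweep.

Everything is float64: the test oracles compare against dense linear-algebra
references at tolerances around 1e-6..1e-10, and the model sizes involved
make the extra precision essentially free.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "stack",
    "rows",
    "embedding_lookup",
    "segment_sum",
    "segment_max",
    "unfold1d",
    "dropout",
]


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading axes that were added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data: np.ndarray = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction -----------------------------------------------------
    @staticmethod
    def _op(data, parents: Sequence["Tensor"], backward) -> "Tensor":
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

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd ----------------------------------------------------------
    def backward(self) -> None:
        """Backpropagate from this tensor (seeded with ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                g = _unbroadcast(g, parent.data.shape)
                parent.grad = g if parent.grad is None else parent.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ---------------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        o = self._coerce(other)
        return Tensor._op(self.data + o.data, (self, o), lambda g: (g, g))

    __radd__ = __add__

    def __neg__(self):
        return Tensor._op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        o = self._coerce(other)
        return Tensor._op(self.data - o.data, (self, o), lambda g: (g, -g))

    def __rsub__(self, other):
        return self._coerce(other) - self

    def __mul__(self, other):
        o = self._coerce(other)
        return Tensor._op(
            self.data * o.data, (self, o), lambda g: (g * o.data, g * self.data)
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._coerce(other)
        return Tensor._op(
            self.data / o.data,
            (self, o),
            lambda g: (g / o.data, -g * self.data / (o.data**2)),
        )

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)
        return Tensor._op(
            self.data**e, (self,), lambda g: (g * e * self.data ** (e - 1),)
        )

    def __matmul__(self, other):
        o = self._coerce(other)
        a, b = self.data, o.data
        if b.ndim != 2:
            raise ValueError("matmul right operand must be 2-D")
        out = a @ b

        def bw(g):
            ga = g @ b.T
            if a.ndim == 2:
                gb = a.T @ g
            else:  # batched (..., m, k) @ (k, n)
                gb = np.tensordot(a, g, axes=(tuple(range(a.ndim - 1)),) * 2)
            return ga, gb

        return Tensor._op(out, (self, o), bw)

    # -- nonlinearities ------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        return Tensor._op(self.data * mask, (self,), lambda g: (g * mask,))

    def leaky_relu(self, slope: float = 0.2):
        mask = np.where(self.data > 0, 1.0, slope)
        return Tensor._op(self.data * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self):
        out = np.empty_like(self.data)
        pos = self.data >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-self.data[pos]))
        ex = np.exp(self.data[~pos])
        out[~pos] = ex / (1.0 + ex)
        return Tensor._op(out, (self,), lambda g: (g * out * (1.0 - out),))

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor._op(out, (self,), lambda g: (g * (1.0 - out**2),))

    def exp(self):
        out = np.exp(self.data)
        return Tensor._op(out, (self,), lambda g: (g * out,))

    def log(self):
        return Tensor._op(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor._op(out, (self,), lambda g: (g / (2.0 * out),))

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        return Tensor._op(out, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int):
        """Maximum along ``axis``; gradient flows to the (first) argmax."""
        am = np.expand_dims(self.data.argmax(axis=axis), axis)
        out = np.take_along_axis(self.data, am, axis=axis).squeeze(axis)

        def bw(g):
            gx = np.zeros_like(self.data)
            np.put_along_axis(gx, am, np.expand_dims(g, axis), axis=axis)
            return (gx,)

        return Tensor._op(out, (self,), bw)

    # -- shape manipulation ----------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor._op(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(old),)
        )

    def slice_last(self, start: int, stop: int):
        """Slice ``[..., start:stop]`` along the last axis."""
        out = self.data[..., start:stop]

        def bw(g):
            gx = np.zeros_like(self.data)
            gx[..., start:stop] = g
            return (gx,)

        return Tensor._op(out, (self,), bw)

    def select_time(self, t: int):
        """``x[:, t, :]`` for a (B, T, D) tensor."""
        out = self.data[:, t, :]

        def bw(g):
            gx = np.zeros_like(self.data)
            gx[:, t, :] = g
            return (gx,)

        return Tensor._op(out, (self,), bw)


# -- free functions -------------------------------------------------------


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        return tuple(
            np.take(g, np.arange(offsets[i], offsets[i + 1]), axis=axis)
            for i in range(len(datas))
        )

    return Tensor._op(out, tuple(tensors), bw)


def stack(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    out = np.stack([t.data for t in tensors], axis=axis)

    def bw(g):
        return tuple(np.take(g, i, axis=axis) for i in range(len(tensors)))

    return Tensor._op(out, tuple(tensors), bw)


def rows(t: Tensor, index: np.ndarray) -> Tensor:
    """Gather rows (axis 0) by integer index; scatter-add on the way back."""
    index = np.asarray(index, dtype=np.intp)
    out = t.data[index]

    def bw(g):
        gx = np.zeros_like(t.data)
        np.add.at(gx, index, g)
        return (gx,)

    return Tensor._op(out, (t,), bw)


def embedding_lookup(weight: Tensor, codes: np.ndarray, padding_idx: int = 0) -> Tensor:
    """Row lookup for integer code arrays; the padding row receives no gradient."""
    codes = np.asarray(codes, dtype=np.intp)
    out = weight.data[codes]

    def bw(g):
        gw = np.zeros_like(weight.data)
        np.add.at(gw, codes, g)
        if padding_idx is not None:
            gw[padding_idx] = 0.0
        return (gw,)

    return Tensor._op(out, (weight,), bw)


def segment_sum(t: Tensor, index: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``t`` into ``num_segments`` buckets given by ``index``."""
    index = np.asarray(index, dtype=np.intp)
    out = np.zeros((num_segments,) + t.data.shape[1:], dtype=np.float64)
    np.add.at(out, index, t.data)

    def bw(g):
        return (g[index],)

    return Tensor._op(out, (t,), bw)


def segment_max(t: Tensor, index: np.ndarray, num_segments: int) -> Tensor:
    """Per-segment coordinate-wise maximum.

    Every segment must be non-empty.  Gradient is split evenly among tied
    maxima (a valid subgradient; ties are rare for continuous activations).
    """
    index = np.asarray(index, dtype=np.intp)
    counts = np.bincount(index, minlength=num_segments)
    if np.any(counts == 0):
        raise ValueError("segment_max: empty segment")
    out = np.full((num_segments,) + t.data.shape[1:], -np.inf)
    np.maximum.at(out, index, t.data)

    def bw(g):
        is_max = (t.data == out[index]).astype(np.float64)
        tie_count = np.zeros_like(out)
        np.add.at(tie_count, index, is_max)
        return (is_max * (g / tie_count)[index],)

    return Tensor._op(out, (t,), bw)


def unfold1d(t: Tensor, kernel: int) -> Tensor:
    """(B, T, D) -> (B, T-k+1, k*D) sliding windows along the time axis."""
    b, length, dim = t.data.shape
    if kernel > length:
        raise ValueError(f"kernel width {kernel} exceeds sequence length {length}")
    n_out = length - kernel + 1
    idx = np.arange(n_out)[:, None] + np.arange(kernel)[None, :]
    out = t.data[:, idx, :].reshape(b, n_out, kernel * dim)

    def bw(g):
        g4 = g.reshape(b, n_out, kernel, dim)
        gx = np.zeros_like(t.data)
        for j in range(kernel):  # kernel is small (<= 8)
            gx[:, j : j + n_out, :] += g4[:, :, j, :]
        return (gx,)

    return Tensor._op(out, (t,), bw)


def dropout(t: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; call only in training mode with rate > 0."""
    keep = 1.0 - rate
    mask = (rng.random(t.data.shape) < keep) / keep
    return t * Tensor(mask)
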