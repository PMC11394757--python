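"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains a point-cloud graph neural network whose computation
graph is a DAG of affine maps, ReLU nonlinearities, row gather/scatter
between point, pair and vertex index spaces, and sorted segment
reductions (sum for the chemical-feature aggregation, max for the
neighbourhood/edge aggregation).  This module provides exactly those
operations on a small tape-based ``Tensor`` with a topological-order
``backward``.

Ops are fused where it saves memory traffic (``affine`` computes
``act(x @ W + b)`` in one pass; gradient accumulation takes ownership of
freshly allocated arrays instead of copying).  All tensors are float32;
index arrays are int64 and never differentiated.  Segment reductions
require segment ids sorted ascending with every segment in
``0..num_segments-1`` non-empty — callers compact ids first.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph utilities ---------------------------------------------------

    def _accumulate(self, g, own: bool = False):
        """Add ``g`` to the gradient.  ``own=True`` promises ``g`` is a
        freshly allocated array this tensor may keep and mutate."""
        if self.grad is None:
            g = np.asarray(g, dtype=DTYPE)
            self.grad = g if own else g.copy()
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()
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
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()
            if t._prev:  # free intermediate grads/tape as soon as consumed
                t.grad = None
                t._backward = None
                t._prev = ()

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, True, (self, other))

        def _backward():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad, other.data.shape))

        out._backward = _backward
        return out

    def __mul__(self, scalar: float):
        s = float(scalar)
        out = Tensor(self.data * s, True, (self,))

        def _backward():
            if self.requires_grad:
                self._accumulate(out.grad * s, own=True)

        out._backward = _backward
        return out

    __rmul__ = __mul__

    def __matmul__(self, other: "Tensor"):
        out = Tensor(self.data @ other.data, True, (self, other))

        def _backward():
            if self.requires_grad:
                self._accumulate(out.grad @ other.data.T, own=True)
            if other.requires_grad:
                other._accumulate(self.data.T @ out.grad, own=True)

        out._backward = _backward
        return out


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    g = grad
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def constant(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=DTYPE), requires_grad=False)


def _stable_sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def affine(x: Tensor, W: Tensor, b: Tensor = None, activation: str = None) -> Tensor:
    """Fused ``act(x @ W + b)`` with act in {None, "relu"}."""
    data = x.data @ W.data
    if b is not None:
        data += b.data
    if activation == "relu":
        np.maximum(data, 0.0, out=data)
    elif activation is not None:
        raise ValueError(f"unknown activation {activation!r}")
    prev = (x, W) if b is None else (x, W, b)
    out = Tensor(data, True, prev)

    def _backward():
        go = out.grad
        if activation == "relu":
            go = go * (out.data > 0)
        if b is not None and b.requires_grad:
            b._accumulate(go.sum(axis=0), own=True)
        if W.requires_grad:
            W._accumulate(x.data.T @ go, own=True)
        if x.requires_grad:
            x._accumulate(go @ W.data.T, own=True)

    out._backward = _backward
    return out


def add_bias_relu(a: Tensor, b: Tensor, bias: Tensor) -> Tensor:
    """Fused ``relu(a + b + bias)`` for equal-shaped a, b and a 1-D bias."""
    data = a.data + b.data
    data += bias.data
    np.maximum(data, 0.0, out=data)
    out = Tensor(data, True, (a, b, bias))

    def _backward():
        go = out.grad * (out.data > 0)
        if bias.requires_grad:
            bias._accumulate(go.sum(axis=0), own=True)
        if a.requires_grad:
            a._accumulate(go, own=True)
        if b.requires_grad:
            b._accumulate(go, own=(not a.requires_grad))

    out._backward = _backward
    return out


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), True, (x,))

    def _backward():
        if x.requires_grad:
            x._accumulate(out.grad * (x.data > 0), own=True)

    out._backward = _backward
    return out


def sigmoid(x: Tensor) -> Tensor:
    p = _stable_sigmoid(x.data)
    out = Tensor(p, True, (x,))

    def _backward():
        if x.requires_grad:
            x._accumulate(out.grad * p * (1.0 - p), own=True)

    out._backward = _backward
    return out


def concat(tensors, axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), True,
                 tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _backward():
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(a, b)
                t._accumulate(np.ascontiguousarray(out.grad[tuple(sl)]),
                              own=True)

    out._backward = _backward
    return out


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """``out[k] = x[idx[k]]``; backward scatter-adds into ``x``."""
    idx = np.asarray(idx, dtype=np.int64)
    out = Tensor(x.data[idx], True, (x,))

    def _backward():
        if x.requires_grad:
            x._accumulate(_scatter_add(out.grad, idx, x.data.shape[0]),
                          own=True)

    out._backward = _backward
    return out


def scatter_rows(x: Tensor, idx: np.ndarray, num_rows: int) -> Tensor:
    """Place row ``k`` of ``x`` at row ``idx[k]`` of a zero (num_rows, D)
    array.  ``idx`` must contain no duplicates; backward is a gather."""
    idx = np.asarray(idx, dtype=np.int64)
    data = np.zeros((num_rows,) + x.data.shape[1:], dtype=DTYPE)
    data[idx] = x.data
    out = Tensor(data, True, (x,))

    def _backward():
        if x.requires_grad:
            x._accumulate(out.grad[idx], own=True)

    out._backward = _backward
    return out


def _scatter_add(values, idx, num_rows):
    """Sum rows of ``values`` sharing an index, via sort + reduceat."""
    out = np.zeros((num_rows,) + values.shape[1:], dtype=DTYPE)
    if idx.size == 0:
        return out
    order = np.argsort(idx, kind="stable")
    sorted_idx = idx[order]
    starts = np.flatnonzero(np.r_[True, sorted_idx[1:] != sorted_idx[:-1]])
    out[sorted_idx[starts]] = np.add.reduceat(values[order], starts, axis=0)
    return out


def _segment_starts(segment_ids, num_segments):
    starts = np.flatnonzero(np.r_[True, segment_ids[1:] != segment_ids[:-1]])
    if starts.size != num_segments or not np.array_equal(
            segment_ids[starts], np.arange(num_segments)):
        raise ValueError("segment ids must be sorted and cover every segment")
    return starts


def segment_sum(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    segment_ids = np.asarray(segment_ids, dtype=np.int64)
    starts = _segment_starts(segment_ids, num_segments)
    out = Tensor(np.add.reduceat(x.data, starts, axis=0), True, (x,))

    def _backward():
        if x.requires_grad:
            x._accumulate(out.grad[segment_ids], own=True)

    out._backward = _backward
    return out


def segment_max(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Elementwise max over each segment; ties share the gradient equally."""
    segment_ids = np.asarray(segment_ids, dtype=np.int64)
    starts = _segment_starts(segment_ids, num_segments)
    maxv = np.maximum.reduceat(x.data, starts, axis=0)
    out = Tensor(maxv, True, (x,))

    def _backward():
        if x.requires_grad:
            hit = (x.data == maxv[segment_ids])
            counts = np.add.reduceat(hit.astype(DTYPE), starts, axis=0)
            g = (out.grad / counts)[segment_ids]
            g *= hit
            x._accumulate(g, own=True)

    out._backward = _backward
    return out


def bce_with_logits(logits: Tensor, labels: np.ndarray,
                    pos_weight: float = 1.0) -> Tensor:
    """Mean binary cross-entropy from logits, with a positive-class weight.

    ``loss_i = w * y_i * softplus(-z_i) + (1 - y_i) * softplus(z_i)``,
    averaged over samples.  Numerically stable for large |z|.
    """
    z = logits.data.ravel()
    y = np.asarray(labels, dtype=DTYPE).ravel()
    if z.shape != y.shape:
        raise ValueError("logits and labels must have matching length")
    w = float(pos_weight)
    per = w * y * np.logaddexp(0.0, -z) + (1.0 - y) * np.logaddexp(0.0, z)
    out = Tensor(per.mean(), True, (logits,))
    n = z.size

    def _backward():
        if logits.requires_grad:
            p = _stable_sigmoid(z)
            g = ((1.0 - y) * p - w * y * (1.0 - p)) * (out.grad.item() / n)
            logits._accumulate(g.reshape(logits.data.shape), own=True)

    out._backward = _backward
    return out
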