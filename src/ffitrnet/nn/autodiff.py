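"""A compact reverse-mode automatic-differentiation engine on NumPy arrays.

Supports exactly the operations the model needs: broadcasted arithmetic,
(batched) matrix multiplication, elementwise nonlinearities, reductions,
reshapes/transposes, row gather and segment-sum scatter.  Gradients are
accumulated in float64 and verified against central finite differences in the
test suite.

Design notes
------------
* ``Tensor`` wraps an ``np.ndarray``; the graph is built eagerly and freed
  after ``backward``.
* Broadcasting is undone on the backward pass by summing gradients over
  broadcast axes (``_unbroadcast``).
* ``gather``/``segment_sum`` are exact adjoints of each other, which is what
  sparse per-pair attention over molecular graphs needs.
"""

from __future__ import annotations

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size-1 in the original
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Array | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _accum(self, grad: Array) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data: Array, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = parents
            out._backward = backward
        return out

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(out):
            if self.requires_grad:
                self._accum(-out.grad)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-out.grad * self.data / other.data**2, other.shape)
                )

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * p * self.data ** (p - 1))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(out):
            if self.requires_grad:
                ga = out.grad @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ out.grad
                other._accum(_unbroadcast(gb, other.shape))

        return self._make(out_data, (self, other), backward)

    # -- elementwise ---------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * out.data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(out):
            if self.requires_grad:
                self._accum(out.grad / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * 0.5 / out.data)

        return self._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * (1.0 - out.data**2))

        return self._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * mask)

        return self._make(self.data * mask, (self,), backward)

    # -- reductions / shape --------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(out):
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        old = self.shape

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    # -- sparse graph ops ----------------------------------------------------
    def gather(self, idx: Array):
        """Select rows along axis 0: out[p] = self[idx[p]]."""
        idx = np.asarray(idx, dtype=np.int64)

        def backward(out):
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accum(g)

        return self._make(self.data[idx], (self,), backward)

    def segment_sum(self, idx: Array, num_segments: int):
        """Scatter-add rows into `num_segments` bins: out[idx[p]] += self[p]."""
        idx = np.asarray(idx, dtype=np.int64)
        out_data = np.zeros((num_segments,) + self.shape[1:])
        np.add.at(out_data, idx, self.data)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad[idx])

        return self._make(out_data, (self,), backward)

    # -- autodiff driver -----------------------------------------------------
    def backward(self, grad: Array | None = None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative post-order: molecules give deep graphs
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node)
        for node in topo:  # free the graph
            node._backward = None
            node._prev = ()


# ---------------------------------------------------------------------------
# Composite functions
# ---------------------------------------------------------------------------

def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (the shift is a detached constant)."""
    shift = np.max(x.data, axis=axis, keepdims=True)
    e = (x - Tensor(shift)).exp()
    return e / e.sum(axis=axis, keepdims=True)


def segment_softmax(logits: Tensor, idx: Array, num_segments: int) -> Tensor:
    """Softmax over rows sharing the same segment id (per source atom).

    ``logits`` is (P, ...) with pair axis first; normalization runs over all
    rows p with idx[p] == s, independently per trailing column.
    """
    idx = np.asarray(idx, dtype=np.int64)
    seg_max = np.full((num_segments,) + logits.shape[1:], -np.inf)
    np.maximum.at(seg_max, idx, logits.data)
    e = (logits - Tensor(seg_max[idx])).exp()
    denom = e.segment_sum(idx, num_segments).gather(idx)
    return e / denom


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis, then scale and shift."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc / ((var + eps) ** 0.5) * gain + bias


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    out = x @ w
    return out if b is None else out + b


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when rate == 0 or rng is None (inference)."""
    if rate <= 0.0 or rng is None:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)
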