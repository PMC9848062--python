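"""Reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float64 ndarray and records the operations applied
to it; :meth:`Tensor.backward` walks the graph in reverse topological order
and accumulates exact gradients.  The op set is exactly what the affinity
model needs: elementwise arithmetic, (batched) matmul, reductions, reshapes,
gather / segment-sum for graph message passing, sliding windows for 1-D
convolution, and numerically stable softmax / log-sum-exp style primitives.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading added axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    # -- graph bookkeeping ---------------------------------------------------
    def _make(self, data: np.ndarray, parents: tuple["Tensor", ...], backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = parents
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free the closure once used; keeps long loops from leaking
                node._backward = None
                node._prev = ()

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(g)
        else:
            self.grad = self.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(
                _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
            )

        return self._make(out_data, (self, other), backward)

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:
                self._accum(g * b)
                other._accum(g * a)
                return
            ga = g @ np.swapaxes(b, -1, -2) if b.ndim > 1 else np.outer(g, b)
            gb = np.swapaxes(a, -1, -2) @ g if a.ndim > 1 else np.outer(a, g)
            self._accum(_unbroadcast(ga, a.shape))
            other._accum(_unbroadcast(gb, b.shape))

        return self._make(out_data, (self, other), backward)

    # -- nonlinearities ------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            self._accum(g * mask)

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def backward(g):
            self._accum(g * s * (1.0 - s))

        return self._make(s, (self,), backward)

    def tanh(self):
        t = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - t * t))

        return self._make(t, (self,), backward)

    def exp(self):
        e = np.exp(self.data)

        def backward(g):
            self._accum(g * e)

        return self._make(e, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def softmax(self, axis: int = -1):
        """Numerically stable softmax along ``axis``."""
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accum(s * (g - dot))

        return self._make(s, (self,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            self._accum(g.reshape(old))

        return self._make(out_data, (self,), backward)

    def swapaxes(self, a: int, b: int):
        out_data = np.swapaxes(self.data, a, b)

        def backward(g):
            self._accum(np.swapaxes(g, a, b))

        return self._make(out_data, (self,), backward)

    def __getitem__(self, key):
        out_data = self.data[key]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accum(full)

        return self._make(out_data, (self,), backward)


# ---------------------------------------------------------------------------
# Free functions
# ---------------------------------------------------------------------------


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
            t._accum(g[tuple(idx)])

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)
        out._backward = backward
    return out


def gather(t: Tensor, index: np.ndarray) -> Tensor:
    """Row gather ``t[index]`` along axis 0 with scatter-add gradient."""
    index = np.asarray(index, dtype=np.intp)
    out_data = t.data[index]

    def backward(g):
        full = np.zeros_like(t.data)
        np.add.at(full, index, g)
        t._accum(full)

    return t._make(out_data, (t,), backward)


def segment_sum(t: Tensor, segment_ids: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of ``t`` into ``n_segments`` buckets given per-row ids."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    out_data = np.zeros((n_segments,) + t.data.shape[1:])
    np.add.at(out_data, segment_ids, t.data)

    def backward(g):
        t._accum(g[segment_ids])

    return t._make(out_data, (t,), backward)


def sliding_windows(t: Tensor, kernel: int, pad: int) -> Tensor:
    """Extract 1-D convolution windows from a (B, L, C) tensor.

    Returns (B, L_out, kernel * C) with zero padding of ``pad`` on both ends;
    the backward pass scatters window gradients back (col2im).
    """
    B, L, C = t.data.shape
    padded = np.pad(t.data, ((0, 0), (pad, pad), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(padded, kernel, axis=1)
    # win: (B, L_out, C, kernel) -> (B, L_out, kernel, C) -> flatten
    win = np.ascontiguousarray(win.transpose(0, 1, 3, 2))
    L_out = win.shape[1]
    out_data = win.reshape(B, L_out, kernel * C)

    def backward(g):
        g = g.reshape(B, L_out, kernel, C)
        gp = np.zeros((B, L + 2 * pad, C))
        for k in range(kernel):
            gp[:, k : k + L_out] += g[:, :, k]
        t._accum(gp[:, pad : pad + L])

    return t._make(out_data, (t,), backward)
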