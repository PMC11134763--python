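"""A minimal reverse-mode automatic-differentiation engine on numpy.

Just enough tape-based autodiff to train and explain the similarity model:
float32 tensors, broadcasting-aware elementwise ops, matmul, reshape,
softmax, layer norm, embedding lookup and dropout. Every node keeps its
gradient after ``backward()`` — the explanation module reads gradients of
intermediate tensors (attention maps, embedded tokens) directly.
"""

from __future__ import annotations

from typing import Callable, Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["Tensor", "concat", "affine"]


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum grad over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    nd_extra = grad.ndim - len(shape)
    if nd_extra > 0:
        grad = grad.sum(axis=tuple(range(nd_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: Tuple["Tensor", ...] = (),
        _backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # ---- graph plumbing -------------------------------------------------
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, g: np.ndarray, own: bool = False) -> None:
        # own=True: g is freshly allocated by the caller and may be adopted
        # without a defensive copy
        if self.grad is None:
            if own and g.dtype == np.float32:
                self.grad = g
            else:
                self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen: set[int] = set()
        stack: List[Tuple[Tensor, bool]] = [(self, False)]
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # ---- ops ------------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))

    def __add__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
                )

        out._backward = bwd
        return out

    def __pow__(self, exponent: float) -> "Tensor":
        out = Tensor(self.data**exponent, _parents=(self,))
        out._backward = lambda g: self._accumulate(
            g * exponent * self.data ** (exponent - 1)
        )
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        out._backward = bwd
        return out

    __matmul__ = matmul

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(orig))
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))
        out._backward = lambda g: self._accumulate(g * (self.data > 0))
        return out

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * y * (1.0 - y))
        return out

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - y * y))
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y, _parents=(self,))

        def bwd(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            self._accumulate(y * (g - dot))

        out._backward = bwd
        return out

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5) -> "Tensor":
        """Normalize over the last axis, then scale and shift."""
        mu = self.data.mean(axis=-1, keepdims=True)
        var = self.data.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (self.data - mu) * inv
        out = Tensor(xhat * gamma.data + beta.data, _parents=(self, gamma, beta))

        def bwd(g):
            if gamma.requires_grad:
                gamma._accumulate(
                    (g * xhat).sum(axis=tuple(range(g.ndim - 1))).astype(np.float32)
                )
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=tuple(range(g.ndim - 1))).astype(np.float32))
            if self.requires_grad:
                gx = g * gamma.data
                d = self.data.shape[-1]
                term = gx - gx.mean(axis=-1, keepdims=True) - xhat * (
                    gx * xhat
                ).mean(axis=-1, keepdims=True)
                self._accumulate(term * inv)

        out._backward = bwd
        return out

    def embedding(self, idx: np.ndarray) -> "Tensor":
        """Treat self as an embedding table; gather rows by integer index."""
        idx = np.asarray(idx)
        out = Tensor(self.data[idx], _parents=(self,))

        def bwd(g):
            gw = np.zeros_like(self.data)
            np.add.at(gw, idx.reshape(-1), g.reshape(-1, self.data.shape[-1]))
            self._accumulate(gw)

        out._backward = bwd
        return out

    def dropout(self, p: float, rng: np.random.Generator, training: bool) -> "Tensor":
        if not training or p <= 0.0:
            return self
        # keep = floor(u + (1-p)) is 1 when u >= p else 0; all in-place f32
        keep = rng.random(self.data.shape, dtype=np.float32)
        keep += 1.0 - p
        np.floor(keep, out=keep)
        keep *= 1.0 / (1.0 - p)
        out = Tensor(self.data * keep, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * keep, own=True)
        return out

    def add_bias_mask(self, mask_bias: np.ndarray) -> "Tensor":
        """Add a constant additive mask (e.g. -1e9 on padded keys)."""
        out = Tensor(self.data + mask_bias.astype(np.float32), _parents=(self,))
        out._backward = lambda g: self._accumulate(g)
        return out

    def __getitem__(self, key) -> "Tensor":
        out = Tensor(self.data[key], _parents=(self,))

        def bwd(g):
            gx = np.zeros_like(self.data)
            gx[key] = g
            self._accumulate(gx)

        out._backward = bwd
        return out

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def affine(x: Tensor, W: Tensor, b: Tensor, relu: bool = False) -> Tensor:
    """Fused ``x @ W + b`` with optional ReLU: single output buffer, and a
    backward pass that computes all three input gradients with fresh arrays.
    ``x`` must be 2-D (callers reshape batch dims away for one big GEMM)."""
    out_data = x.data @ W.data
    out_data += b.data
    if relu:
        np.maximum(out_data, 0.0, out=out_data)
    out = Tensor(out_data, _parents=(x, W, b))

    def bwd(g):
        if relu:
            g = g * (out_data > 0)
        if x.requires_grad:
            x._accumulate(g @ W.data.T, own=True)
        if W.requires_grad:
            W._accumulate(x.data.T @ g, own=True)
        if b.requires_grad:
            b._accumulate(g.sum(axis=0), own=True)

    out._backward = bwd
    return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    out._backward = bwd
    return out
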