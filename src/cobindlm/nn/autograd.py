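"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operator set needed by the co-binding language model,
its task heads, and the contact-map CNN: broadcast arithmetic, batched matmul,
softmax, reductions, embedding lookup, and 2-D convolution.  Gradients
accumulate into ``Tensor.grad`` after :meth:`Tensor.backward` on a scalar.

A module-level ``no_grad`` context disables graph construction for inference.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph building (inference / embedding extraction)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "_grad_owned")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()
        self._grad_owned = False

    def _coerce(self, other) -> "Tensor":
        """Wrap scalars at this tensor's dtype so float32 graphs stay float32."""
        if isinstance(other, Tensor):
            return other
        if np.isscalar(other):
            return Tensor(np.asarray(other, dtype=self.data.dtype))
        return Tensor(other)

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, g):
        if self.requires_grad:
            if self.grad is None:
                # store without copying; copy lazily on the rare second accumulation
                self.grad = g if g.dtype == self.data.dtype else g.astype(self.data.dtype)
                self._grad_owned = False
            elif self._grad_owned:
                self.grad += g
            else:
                self.grad = self.grad + g
                self._grad_owned = True

    def zero_grad(self):
        self.grad = None

    # -- helpers -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self):
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._coerce(other) ** -1.0

    def __rtruediv__(self, other):
        return self._coerce(other) * self**-1.0

    def __pow__(self, exponent: float):
        exponent = float(exponent)
        out_data = self.data**exponent

        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1.0))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data
        a, b = self, other

        def backward(g):
            if b.data.ndim == 1:
                if a.data.ndim == 1:
                    a._accum(g * b.data)
                    b._accum(g * a.data)
                    return
                a._accum(np.expand_dims(g, -1) * b.data)
                b._accum(_unbroadcast(
                    (a.data * np.expand_dims(g, -1)).reshape(-1, b.data.shape[0]).sum(0),
                    b.data.shape))
                return
            if a.data.ndim == 1:
                a._accum(g @ np.swapaxes(b.data, -1, -2))
                b._accum(_unbroadcast(np.outer(a.data, g), b.data.shape))
                return
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            a._accum(_unbroadcast(ga, a.data.shape))
            b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            self._accum(g.reshape(orig))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._make(out_data, (self,), backward)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int):
        """Max-reduce along one axis; gradient flows to (first) argmax."""
        out_data = self.data.max(axis=axis)
        arg = self.data.argmax(axis=axis)

        def backward(g):
            full = np.zeros_like(self.data)
            idx = list(np.indices(out_data.shape))
            idx.insert(axis if axis >= 0 else self.data.ndim + axis, arg)
            full[tuple(idx)] = g
            self._accum(full)

        return Tensor._make(out_data, (self,), backward)

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self, eps: float = 0.0):
        """Natural log; ``eps`` clamps the argument away from zero."""
        arg = np.maximum(self.data, eps) if eps else self.data
        out_data = np.log(arg)

        def backward(g):
            self._accum(g / arg * (self.data >= (eps if eps else -np.inf)))

        return Tensor._make(out_data, (self,), backward)

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        p = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * p).sum(axis=axis, keepdims=True)
            self._accum(p * (g - dot))

        return Tensor._make(p, (self,), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


def embedding_lookup(table: Tensor, indices: np.ndarray) -> Tensor:
    """Row lookup with scatter-add gradient into the table."""
    indices = np.asarray(indices)
    out_data = table.data[indices]

    def backward(g):
        full = np.zeros_like(table.data)
        np.add.at(full, indices, g)
        table._accum(full)

    return Tensor._make(out_data, (table,), backward)


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(B, C, H, W) -> (B, H, W, C*k*k) patch matrix with zero padding."""
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    B, C, H, W = x.shape
    # (B, C, H, W, k, k) -> (B, H, W, C*k*k)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(B, H, W, C * k * k)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, pad: int) -> Tensor:
    """'Same'-style 2-D convolution (cross-correlation), stride 1.

    x: (B, C_in, H, W); weight: (C_out, C_in, k, k); bias: (C_out,).
    """
    B, C_in, H, W = x.data.shape
    C_out, _, k, _ = weight.data.shape
    cols = _im2col(x.data, k, pad)  # (B, H, W, C_in*k*k)
    wmat = weight.data.reshape(C_out, -1)  # (C_out, C_in*k*k)
    out = cols @ wmat.T  # (B, H, W, C_out)
    if bias is not None:
        out = out + bias.data
    out = out.transpose(0, 3, 1, 2)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        # g: (B, C_out, H, W)
        gmat = g.transpose(0, 2, 3, 1).reshape(-1, C_out)  # (B*H*W, C_out)
        if weight.requires_grad:
            gw = gmat.T @ cols.reshape(-1, C_in * k * k)
            weight._accum(gw.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(gmat.sum(axis=0))
        if x.requires_grad:
            # dx = full correlation of g with spatially flipped, channel-swapped kernels
            wflip = weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C_in, C_out, k, k)
            gcols = _im2col(g, k, k - 1 - pad)
            gx = gcols @ wflip.reshape(C_in, -1).T  # (B, H, W, C_in)
            x._accum(gx.transpose(0, 3, 1, 2))

    return Tensor._make(out, parents, backward)
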