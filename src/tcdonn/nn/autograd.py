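"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine provides exactly the primitives the Self-ONN architectures need:
broadcast arithmetic, batched matmul, elementwise integer powers (the Taylor
expansion of a generative neuron), tanh, strided 1D convolution, softmax /
log-softmax, and shape ops.  Gradients are accumulated by topological sort
over the recorded graph, as in any tape-based framework.

Data is float32 by default (see `set_default_dtype` / `dtype_context`);
determinism follows from numpy's own determinism for a fixed sequence of
operations.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "conv1d", "taylor_expand", "concat", "default_dtype",
           "set_default_dtype", "dtype_context"]

# float32 keeps training memory-bandwidth-bound steps fast; float64 is
# available for gradient checking.
_DTYPE = np.float32


def default_dtype():
    return _DTYPE


def set_default_dtype(dtype) -> None:
    global _DTYPE
    _DTYPE = np.dtype(dtype).type


@contextmanager
def dtype_context(dtype):
    global _DTYPE
    old = _DTYPE
    set_default_dtype(dtype)
    try:
        yield
    finally:
        _DTYPE = old


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # ---- graph construction -------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # ---- backward pass ------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep residual graphs overflow recursion
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad or pg is None:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg
            # leaves with a backward do not occur; interior grads are discarded

    # ---- arithmetic ---------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other
        out_data = a.data + b.data

        def backward(g):
            return (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape))

        return Tensor._make(out_data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other
        out_data = a.data * b.data

        def backward(g):
            return (_unbroadcast(g * b.data, a.shape),
                    _unbroadcast(g * a.data, b.shape))

        return Tensor._make(out_data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        a, b = self, other
        out_data = a.data / b.data

        def backward(g):
            return (_unbroadcast(g / b.data, a.shape),
                    _unbroadcast(-g * a.data / (b.data ** 2), b.shape))

        return Tensor._make(out_data, (a, b), backward)

    def __matmul__(self, other):
        other = self._coerce(other)
        a, b = self, other
        out_data = a.data @ b.data

        def backward(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        return Tensor._make(out_data, (a, b), backward)

    def pow_int(self, q: int) -> "Tensor":
        if int(q) != q or q < 1:
            raise ValueError("pow_int expects a positive integer exponent")
        a = self
        out_data = a.data ** q

        def backward(g):
            return (g * q * a.data ** (q - 1),)

        return Tensor._make(out_data, (a,), backward)

    def sqrt(self) -> "Tensor":
        a = self
        out_data = np.sqrt(a.data)

        def backward(g):
            return (g * 0.5 / np.sqrt(a.data),)

        return Tensor._make(out_data, (a,), backward)

    def tanh(self) -> "Tensor":
        a = self
        out_data = np.tanh(a.data)

        def backward(g):
            return (g * (1.0 - out_data ** 2),)

        return Tensor._make(out_data, (a,), backward)

    def exp(self) -> "Tensor":
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            return (g * out_data,)

        return Tensor._make(out_data, (a,), backward)

    # ---- reductions and shape ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, a.shape).copy(),)
            g_exp = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g_exp, a.shape).copy(),)

        return Tensor._make(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        out_data = a.data.reshape(shape)

        def backward(g):
            return (g.reshape(a.shape),)

        return Tensor._make(out_data, (a,), backward)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)
        out_data = a.data.transpose(axes)

        def backward(g):
            return (g.transpose(inv),)

        return Tensor._make(out_data, (a,), backward)

    # ---- softmax family -----------------------------------------------------

    def log_softmax(self) -> "Tensor":
        """Log-softmax over the last axis."""
        a = self
        shifted = a.data - a.data.max(axis=-1, keepdims=True)
        logz = np.log(np.exp(shifted).sum(axis=-1, keepdims=True))
        out_data = shifted - logz
        probs = np.exp(out_data)

        def backward(g):
            return (g - probs * g.sum(axis=-1, keepdims=True),)

        return Tensor._make(out_data, (a,), backward)

    def softmax(self) -> "Tensor":
        """Softmax over the last axis."""
        a = self
        out_data = a.data - a.data.max(axis=-1, keepdims=True)
        np.exp(out_data, out=out_data)
        out_data /= out_data.sum(axis=-1, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=-1, keepdims=True)
            return (out_data * (g - dot),)

        return Tensor._make(out_data, (a,), backward)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


# ---- free-function primitives ----------------------------------------------


def taylor_expand(x: Tensor, Q: int) -> Tensor:
    """Stack elementwise powers 1..Q of a (batch, channel, time) tensor.

    Output channel i*Q + (q-1) holds input channel i raised to power q, i.e.
    powers are grouped per input channel.  This is the input expansion that
    turns an operational convolution into a plain convolution over C*Q
    channels.
    """
    if int(Q) != Q or Q < 1:
        raise ValueError("Taylor order Q must be a positive integer")
    B, C, L = x.shape
    xd = x.data
    powers = np.empty((B, C, Q, L), dtype=xd.dtype)
    powers[:, :, 0] = xd
    for q in range(1, Q):
        powers[:, :, q] = powers[:, :, q - 1] * xd
    out_data = powers.reshape(B, C * Q, L)

    def backward(g):
        gq = g.reshape(B, C, Q, L)
        gx = gq[:, :, 0].copy()
        for q in range(2, Q + 1):
            gx += gq[:, :, q - 1] * q * powers[:, :, q - 2]
        return (gx,)

    return Tensor._make(out_data, (x,), backward)


def conv1d(x: Tensor, weight: Tensor, bias: Tensor | None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """Cross-correlation of (B, C, L) input with an (O, C, K) kernel.

    Zero padding on both ends; output length floor((L + 2p - K)/stride) + 1.
    Implemented as im2col + GEMM so the hot path runs in BLAS.
    """
    B, C, L = x.shape
    O, C_w, K = weight.shape
    if C != C_w:
        raise ValueError(f"input has {C} channels but kernel expects {C_w}")
    L_out = (L + 2 * padding - K) // stride + 1
    if L_out < 1:
        raise ValueError("input shorter than kernel: empty valid output")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding))) if padding else x.data
    win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)[:, :, ::stride]
    cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(B, L_out, C * K)
    wmat = weight.data.reshape(O, C * K)
    out = cols @ wmat.T  # (B, L_out, O)
    if bias is not None:
        out += bias.data
    out_data = np.ascontiguousarray(out.transpose(0, 2, 1))
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gl = np.ascontiguousarray(g.transpose(0, 2, 1))  # (B, L_out, O)
        gw = gl.reshape(-1, O).T @ cols.reshape(-1, C * K)
        gcols = (gl @ wmat).reshape(B, L_out, C, K).transpose(0, 2, 1, 3)
        gxp = np.zeros((B, C, L + 2 * padding), dtype=gl.dtype)
        for k in range(K):
            gxp[:, :, k:k + stride * L_out:stride] += gcols[:, :, :, k]
        gx = gxp[:, :, padding:padding + L] if padding else gxp
        gb = gl.sum(axis=(0, 1)) if bias is not None else None
        grads = (gx, gw.reshape(O, C_w, K))
        return grads if bias is None else grads + (gb,)

    return Tensor._make(out_data, parents, backward)


def batch_norm_train(x: Tensor, gamma: Tensor, beta: Tensor,
                     eps: float = 1e-5):
    """Fused training-mode batch normalization over (batch, time) per channel.

    Returns (output, batch_mean, batch_var) — the biased statistics are
    plain arrays for the caller's running-average bookkeeping.  Fusing the
    whole normalization into one node keeps the graph small on the training
    hot path.
    """
    B, C, L = x.shape
    n = B * L
    mean = x.data.mean(axis=(0, 2), keepdims=True)
    centred = x.data - mean
    var = np.mean(centred * centred, axis=(0, 2), keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = centred * inv_std
    g3 = gamma.data.reshape(1, C, 1)
    out_data = xhat * g3 + beta.data.reshape(1, C, 1)

    def backward(g):
        ggamma = (g * xhat).sum(axis=(0, 2))
        gbeta = g.sum(axis=(0, 2))
        gxhat = g * g3
        s1 = gxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (gxhat * xhat).sum(axis=(0, 2), keepdims=True)
        gx = inv_std / n * (n * gxhat - s1 - xhat * s2)
        return (gx, ggamma, gbeta)

    out = Tensor._make(out_data, (x, gamma, beta), backward)
    return out, mean.ravel(), var.ravel()


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = list(tensors)
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out_data, ts, backward)
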