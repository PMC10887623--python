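"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine provides exactly the operations the disentanglement network
needs: broadcast arithmetic, reductions, elementwise nonlinearities,
strided 2D convolution and its transpose, and edge padding with circular /
reflect / zero modes (the polar angle axis is topologically a circle, so
circular padding along it keeps convolutions seam-free).

Tensors are float32.  A ``Tensor`` records its parents and a backward
closure; ``backward()`` runs a topological sweep.  Gradients only flow into
tensors created with ``requires_grad=True`` (parameters) or into nodes on a
path to one, so inference builds no graph to speak of.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np

__all__ = ["Tensor", "as_tensor", "Parameter"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward: Callable | None = None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- graph mechanics ----------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, grad: np.ndarray) -> None:
        grad = grad.astype(np.float32, copy=False)
        if self.grad is None:
            self.grad = grad.copy() if grad.base is not None else grad
        else:
            self.grad = self.grad + grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() expects a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        exponent = float(exponent)
        out_data = self.data ** exponent

        def bwd(g):
            self._accum(g * exponent * self.data ** (exponent - 1.0))

        return Tensor(out_data, parents=(self,), backward=bwd)

    # -- reductions ---------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, axes)
            self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = math.prod(self.data.shape[a] for a in axes)
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities ----------------------------------
    def abs(self):
        sign = np.sign(self.data)

        def bwd(g):
            self._accum(g * sign)

        return Tensor(np.abs(self.data), parents=(self,), backward=bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g):
            self._accum(g * (1.0 - out_data * out_data))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        factor = np.where(mask, 1.0, slope).astype(np.float32)

        def bwd(g):
            self._accum(g * factor)

        return Tensor(self.data * factor, parents=(self,), backward=bwd)

    def relu(self):
        return self.leaky_relu(0.0)

    def log(self):
        def bwd(g):
            self._accum(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bwd)

    def clip(self, lo: float, hi: float):
        mask = ((self.data > lo) & (self.data < hi)).astype(np.float32)

        def bwd(g):
            self._accum(g * mask)

        return Tensor(np.clip(self.data, lo, hi), parents=(self,), backward=bwd)

    # -- shape ops ----------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape

        def bwd(g):
            self._accum(g.reshape(old))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bwd)

    def pad2d(self, pad_h: int, pad_w: int, mode_h: str = "zero", mode_w: str = "zero"):
        """Pad the last two axes of an NCHW tensor, independently per axis.

        Modes: ``circular`` (wrap), ``reflect`` (no edge repeat), ``zero``.
        """
        x = self.data
        np_modes = {"circular": "wrap", "reflect": "reflect", "zero": "constant"}
        padded = x
        if pad_h:
            padded = np.pad(padded, ((0, 0), (0, 0), (pad_h, pad_h), (0, 0)), mode=np_modes[mode_h])
        if pad_w:
            padded = np.pad(padded, ((0, 0), (0, 0), (0, 0), (pad_w, pad_w)), mode=np_modes[mode_w])
        H, W = x.shape[2], x.shape[3]

        def bwd(g):
            # undo width padding first (reverse order of forward)
            # reflect indices are clipped: numpy repeats the edge when the
            # axis is shorter than the pad width
            if pad_w:
                core = g[:, :, :, pad_w : pad_w + W].copy()
                for j in range(pad_w):
                    left = g[:, :, :, j]
                    right = g[:, :, :, pad_w + W + j]
                    if mode_w == "circular":
                        core[:, :, :, W - pad_w + j] += left
                        core[:, :, :, j] += right
                    elif mode_w == "reflect":
                        core[:, :, :, min(pad_w - j, W - 1)] += left
                        core[:, :, :, max(W - 2 - j, 0)] += right
                g = core
            if pad_h:
                core = g[:, :, pad_h : pad_h + H, :].copy()
                for j in range(pad_h):
                    top = g[:, :, j, :]
                    bot = g[:, :, pad_h + H + j, :]
                    if mode_h == "circular":
                        core[:, :, H - pad_h + j, :] += top
                        core[:, :, j, :] += bot
                    elif mode_h == "reflect":
                        core[:, :, min(pad_h - j, H - 1), :] += top
                        core[:, :, max(H - 2 - j, 0), :] += bot
                g = core
            self._accum(g)

        return Tensor(padded, parents=(self,), backward=bwd)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'yes' if self.requires_grad else 'no'})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def Parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)


# ---------------------------------------------------------------------
# convolution primitives (shared by Conv2d and ConvTranspose2d)
# ---------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int):
    """(N, C, H, W) -> (N, C*kh*kw, Ho*Wo) patch matrix (one copy)."""
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::sh, ::sw]  # (N, C, Ho, Wo, kh, kw)
    n, c, ho, wo = win.shape[:4]
    col = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(
        n, c * kh * kw, ho * wo)
    return col, ho, wo


def conv2d_forward(x: np.ndarray, w: np.ndarray, stride: int, pad: int) -> np.ndarray:
    """Plain strided conv, zero padding ``pad`` (NCHW; w is (F, C, kh, kw))."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    f, c, kh, kw = w.shape
    col, ho, wo = _im2col(x, kh, kw, stride, stride)
    out = w.reshape(f, c * kh * kw) @ col  # (N, F, Ho*Wo)
    return out.reshape(x.shape[0], f, ho, wo)


def conv2d_dx(gout: np.ndarray, w: np.ndarray, stride: int, pad: int,
              x_shape: tuple[int, ...]) -> np.ndarray:
    """Gradient w.r.t. the conv input (also the forward pass of conv-transpose)."""
    n, c, h, wd = x_shape
    f, _, kh, kw = w.shape
    ho, wo = gout.shape[2], gout.shape[3]
    # (K, F) @ (N, F, L) -> (N, K, L), K = C*kh*kw
    gcol = w.reshape(f, c * kh * kw).T @ gout.reshape(n, f, ho * wo)
    gcol = gcol.reshape(n, c, kh, kw, ho, wo)
    hp, wp = h + 2 * pad, wd + 2 * pad
    gx = np.zeros((n, c, hp, wp), dtype=gout.dtype)
    for u in range(kh):
        for v in range(kw):
            gx[:, :, u : u + stride * ho : stride, v : v + stride * wo : stride] += \
                gcol[:, :, u, v]
    if pad:
        gx = gx[:, :, pad : pad + h, pad : pad + wd]
    return np.ascontiguousarray(gx)


def conv2d_dw(x: np.ndarray, gout: np.ndarray, stride: int, pad: int,
              w_shape: tuple[int, ...]) -> np.ndarray:
    """Gradient w.r.t. the conv weight."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    f, c, kh, kw = w_shape
    col, ho, wo = _im2col(x, kh, kw, stride, stride)
    g = gout.reshape(gout.shape[0], f, ho * wo)  # (N, F, L)
    # sum over batch and positions: (F, K)
    gw = np.tensordot(g, col, axes=([0, 2], [0, 2]))
    return gw.reshape(f, c, kh, kw)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    out_data = conv2d_forward(x.data, w.data, stride, pad)
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        if x.requires_grad:
            x._accum(conv2d_dx(g, w.data, stride, pad, x.data.shape))
        if w.requires_grad:
            w._accum(conv2d_dw(x.data, g, stride, pad, w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    return Tensor(out_data, parents=parents, backward=bwd)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 2, pad: int = 1) -> Tensor:
    """Transposed conv: the adjoint of ``conv2d`` with the same stride/pad.

    ``w`` has shape (C_in, C_out, kh, kw); output spatial size is
    ``(H-1)*stride - 2*pad + kh``.
    """
    n, cin, h, wd = x.data.shape
    _, cout, kh, kw = w.data.shape
    ho = (h - 1) * stride - 2 * pad + kh
    wo = (wd - 1) * stride - 2 * pad + kw
    out_data = conv2d_dx(x.data, w.data, stride, pad, (n, cout, ho, wo))
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        if x.requires_grad:
            x._accum(conv2d_forward(g, w.data, stride, pad))
        if w.requires_grad:
            w._accum(conv2d_dw(g, x.data, stride, pad, w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    return Tensor(out_data, parents=parents, backward=bwd)
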