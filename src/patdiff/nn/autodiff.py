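"""Minimal reverse-mode automatic differentiation on numpy arrays.

A tape-based engine providing exactly the primitives the noise-estimation
network needs: broadcasting arithmetic, batched matrix products, reductions,
softmax, GELU, pointwise (1x1), depth-wise and full 3x3 convolutions, pixel
shuffle/unshuffle and shape surgery.  The 3x3 convolutions are computed as
nine shifted multiply-adds on views of the zero-padded array, which keeps
both passes allocation-light and memory-bandwidth bound.

Feature tensors use the NCHW layout throughout.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy.special import erf

Array = np.ndarray

# python floats: weak promotion, so float32 graphs stay float32
_INV_SQRT2 = float(1.0 / np.sqrt(2.0))
_INV_SQRT2PI = float(1.0 / np.sqrt(2.0 * np.pi))


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (),
                 backward: Callable[[Array], None] | None = None):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad: Array | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- graph -------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def accumulate(self, g: Array) -> None:
        # first gradient is adopted by reference (most nodes have a single
        # consumer); a second contribution forces an out-of-place add
        if self.grad is None:
            if g.shape != self.data.shape:
                g = np.broadcast_to(g, self.data.shape)
            self.grad = g
        else:
            self.grad = self.grad + g

    def backward(self, grad: Array | None = None) -> None:
        """Reverse-topological sweep from this node."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- operator sugar (python scalars stay weak: no float32 upcast) ------
    def __add__(self, other):
        if isinstance(other, (int, float)):
            return add_const(self, float(other))
        return add(self, as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return scale(self, float(other))
        return mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return add_const(self, -float(other))
        return add(self, scale(as_tensor(other), -1.0))

    def __rsub__(self, other):
        out = scale(self, -1.0)
        return add_const(out, float(other)) if isinstance(other, (int, float)) \
            else add(as_tensor(other), out)

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return scale(self, 1.0 / float(other))
        return div(self, as_tensor(other))

    def __neg__(self):
        return scale(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, as_tensor(other))

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: Array, shape: tuple[int, ...]) -> Array:
    """Reduce a broadcast gradient back to ``shape``."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# -- arithmetic ------------------------------------------------------------

def scale(a: Tensor, s: float) -> Tensor:
    """Multiply by a python scalar (dtype-preserving)."""
    out = Tensor(a.data * s, parents=(a,))

    def backward(g: Array) -> None:
        if a.requires_grad:
            a.accumulate(g * s)

    out._backward = backward
    return out


def add_const(a: Tensor, c: float) -> Tensor:
    out = Tensor(a.data + c, parents=(a,))

    def backward(g: Array) -> None:
        if a.requires_grad:
            a.accumulate(g)

    out._backward = backward
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, parents=(a, b))

    def backward(g: Array) -> None:
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.data.shape))

    out._backward = backward
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, parents=(a, b))

    def backward(g: Array) -> None:
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._backward = backward
    return out


def div(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data / b.data, parents=(a, b))

    def backward(g: Array) -> None:
        if a.requires_grad:
            a.accumulate(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(-g * a.data / b.data**2, b.data.shape))

    out._backward = backward
    return out


def exp(a: Tensor) -> Tensor:
    out = Tensor(np.exp(a.data), parents=(a,))

    def backward(g: Array) -> None:
        if a.requires_grad:
            a.accumulate(g * out.data)

    out._backward = backward
    return out


def sqrt(a: Tensor) -> Tensor:
    out = Tensor(np.sqrt(a.data), parents=(a,))

    def backward(g: Array) -> None:
        if a.requires_grad:
            a.accumulate(g * 0.5 / out.data)

    out._backward = backward
    return out


def square(a: Tensor) -> Tensor:
    return mul(a, a)


# -- reductions ------------------------------------------------------------

def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), parents=(a,))

    def backward(g: Array) -> None:
        if not a.requires_grad:
            return
        if axis is None:
            a.accumulate(np.broadcast_to(g, a.data.shape).copy())
            return
        axes = axis if isinstance(axis, tuple) else (axis,)
        if not keepdims:
            g = np.expand_dims(g, axes)
        a.accumulate(np.broadcast_to(g, a.data.shape).copy())

    out._backward = backward
    return out


def mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return scale(sum_(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


# -- shape surgery ---------------------------------------------------------

def reshape(a: Tensor, shape) -> Tensor:
    out = Tensor(a.data.reshape(shape), parents=(a,))

    def backward(g: Array) -> None:
        if a.requires_grad:
            a.accumulate(g.reshape(a.data.shape))

    out._backward = backward
    return out


def transpose(a: Tensor, axes) -> Tensor:
    out = Tensor(a.data.transpose(axes), parents=(a,))
    inv = np.argsort(axes)

    def backward(g: Array) -> None:
        if a.requires_grad:
            a.accumulate(g.transpose(inv))

    out._backward = backward
    return out


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g: Array) -> None:
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t.accumulate(piece)

    out._backward = backward
    return out


def pad2d(a: Tensor, pad_h: int, pad_w: int) -> Tensor:
    """Zero-pad the trailing two (spatial) axes on the high side."""
    if pad_h == 0 and pad_w == 0:
        return a
    widths = [(0, 0)] * (a.ndim - 2) + [(0, pad_h), (0, pad_w)]
    out = Tensor(np.pad(a.data, widths), parents=(a,))
    h, w = a.data.shape[-2:]

    def backward(g: Array) -> None:
        if a.requires_grad:
            a.accumulate(g[..., :h, :w])

    out._backward = backward
    return out


def crop2d(a: Tensor, h: int, w: int) -> Tensor:
    out = Tensor(a.data[..., :h, :w], parents=(a,))

    def backward(g: Array) -> None:
        if a.requires_grad:
            full = np.zeros_like(a.data)
            full[..., :h, :w] = g
            a.accumulate(full)

    out._backward = backward
    return out


# -- nonlinearities --------------------------------------------------------

def gelu(a: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    x = a.data
    cdf = 0.5 * (1.0 + erf(x * _INV_SQRT2))
    out = Tensor(x * cdf, parents=(a,))

    def backward(g: Array) -> None:
        if a.requires_grad:
            pdf = _INV_SQRT2PI * np.exp(-0.5 * x * x)
            a.accumulate(g * (cdf + x * pdf))

    out._backward = backward
    return out


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, parents=(a,))

    def backward(g: Array) -> None:
        if a.requires_grad:
            a.accumulate(y * (g - (g * y).sum(axis=axis, keepdims=True)))

    out._backward = backward
    return out


# -- linear algebra --------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product with broadcasting over leading axes."""
    out = Tensor(np.matmul(a.data, b.data), parents=(a, b))

    def backward(g: Array) -> None:
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a.accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b.accumulate(_unbroadcast(gb, b.data.shape))

    out._backward = backward
    return out


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """``x @ w.T (+ b)`` for 2-D inputs (batch, features)."""
    out = matmul(x, transpose(w, (1, 0)))
    return add(out, b) if b is not None else out


# -- slicing ---------------------------------------------------------------

def narrow(a: Tensor, start: int, length: int, axis: int = 1) -> Tensor:
    """Contiguous slice along one axis (scatter-add on the way back)."""
    index = [slice(None)] * a.ndim
    index[axis] = slice(start, start + length)
    index = tuple(index)
    out = Tensor(a.data[index], parents=(a,))

    def backward(g: Array) -> None:
        if a.requires_grad:
            full = np.zeros_like(a.data)
            full[index] = g
            a.accumulate(full)

    out._backward = backward
    return out


# -- convolutions (NCHW) ---------------------------------------------------

def conv1x1_grouped(x: Tensor, w: Tensor, groups: int) -> Tensor:
    """Block-diagonal pointwise convolution.

    ``x`` is (N, G*C, H, W) and ``w`` is (G, C_out, C): each group of C
    input channels is mixed by its own matrix — equivalent to G independent
    1x1 convolutions evaluated in one contraction.
    """
    n, gc, h, wd = x.data.shape
    c = gc // groups
    xg = x.data.reshape(n, groups, c, h, wd)
    out_data = np.einsum("ngchw,goc->ngohw", xg, w.data, optimize=True)
    c_out = w.data.shape[1]
    out = Tensor(out_data.reshape(n, groups * c_out, h, wd), parents=(x, w))

    def backward(g: Array) -> None:
        gg = g.reshape(n, groups, c_out, h, wd)
        if x.requires_grad:
            gx = np.einsum("ngohw,goc->ngchw", gg, w.data, optimize=True)
            x.accumulate(gx.reshape(n, gc, h, wd))
        if w.requires_grad:
            w.accumulate(np.einsum("ngohw,ngchw->goc", gg, xg, optimize=True))

    out._backward = backward
    return out


def conv1x1(x: Tensor, w: Tensor) -> Tensor:
    """Pointwise (channel-mixing) convolution; ``w`` is (C_out, C_in)."""
    out = Tensor(np.einsum("nchw,oc->nohw", x.data, w.data, optimize=True),
                 parents=(x, w))

    def backward(g: Array) -> None:
        if x.requires_grad:
            x.accumulate(np.einsum("nohw,oc->nchw", g, w.data, optimize=True))
        if w.requires_grad:
            w.accumulate(np.einsum("nohw,nchw->oc", g, x.data, optimize=True))

    out._backward = backward
    return out


def _pad1(arr: Array) -> Array:
    """Zero-pad the two trailing axes by one (faster than np.pad)."""
    shape = arr.shape[:-2] + (arr.shape[-2] + 2, arr.shape[-1] + 2)
    out = np.zeros(shape, dtype=arr.dtype)
    out[..., 1:-1, 1:-1] = arr
    return out


def dwconv3x3(x: Tensor, k: Tensor) -> Tensor:
    """Depth-wise 3x3 convolution; ``k`` is (C, 3, 3), zero padding.

    Implemented as nine shifted multiply-adds on views of the padded array,
    which avoids materializing sliding windows.
    """
    h, w_ = x.data.shape[-2:]
    padded = _pad1(x.data)
    out_data = np.zeros_like(x.data)
    for di in range(3):
        for dj in range(3):
            out_data += padded[..., di:di + h, dj:dj + w_] * k.data[:, di, dj, None, None]
    out = Tensor(out_data, parents=(x, k))

    def backward(g: Array) -> None:
        if x.requires_grad:
            gpad = _pad1(g)
            gx = np.zeros_like(x.data)
            for di in range(3):
                for dj in range(3):
                    gx += gpad[..., 2 - di:2 - di + h, 2 - dj:2 - dj + w_] \
                        * k.data[:, di, dj, None, None]
            x.accumulate(gx)
        if k.requires_grad:
            gk = np.empty_like(k.data)
            for di in range(3):
                for dj in range(3):
                    gk[:, di, dj] = (padded[..., di:di + h, dj:dj + w_] * g).sum(
                        axis=(0, 2, 3))
            k.accumulate(gk)

    out._backward = backward
    return out


def conv3x3(x: Tensor, w: Tensor) -> Tensor:
    """Full 3x3 convolution; ``w`` is (C_out, C_in, 3, 3), zero padding."""
    h, w_ = x.data.shape[-2:]
    padded = _pad1(x.data)
    out_data = None
    for di in range(3):
        for dj in range(3):
            term = np.einsum("nchw,oc->nohw", padded[..., di:di + h, dj:dj + w_],
                             w.data[:, :, di, dj], optimize=True)
            out_data = term if out_data is None else out_data + term
    out = Tensor(out_data, parents=(x, w))

    def backward(g: Array) -> None:
        if x.requires_grad:
            gpad = _pad1(g)
            gx = None
            for di in range(3):
                for dj in range(3):
                    term = np.einsum(
                        "nohw,oc->nchw", gpad[..., 2 - di:2 - di + h, 2 - dj:2 - dj + w_],
                        w.data[:, :, di, dj], optimize=True)
                    gx = term if gx is None else gx + term
            x.accumulate(gx)
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for di in range(3):
                for dj in range(3):
                    gw[:, :, di, dj] = np.einsum(
                        "nohw,nchw->oc", g, padded[..., di:di + h, dj:dj + w_],
                        optimize=True)
            w.accumulate(gw)

    out._backward = backward
    return out


# -- pixel shuffle ---------------------------------------------------------

def pixel_unshuffle(x: Tensor, r: int = 2) -> Tensor:
    """(N, C, H, W) -> (N, C r^2, H/r, W/r)."""
    n, c, h, w = x.data.shape
    if h % r or w % r:
        raise ValueError(f"spatial size ({h}, {w}) not divisible by {r}")
    y = reshape(x, (n, c, h // r, r, w // r, r))
    y = transpose(y, (0, 1, 3, 5, 2, 4))
    return reshape(y, (n, c * r * r, h // r, w // r))


def pixel_shuffle(x: Tensor, r: int = 2) -> Tensor:
    """(N, C r^2, H, W) -> (N, C, H r, W r); inverse of pixel_unshuffle."""
    n, c, h, w = x.data.shape
    if c % (r * r):
        raise ValueError(f"channel count {c} not divisible by {r * r}")
    y = reshape(x, (n, c // (r * r), r, r, h, w))
    y = transpose(y, (0, 1, 4, 2, 5, 3))
    return reshape(y, (n, c // (r * r), h * r, w * r))


# -- composites ------------------------------------------------------------

def layernorm_channels(x: Tensor, gain: Tensor, eps: float = 1e-6) -> Tensor:
    """Bias-free layer normalization over the channel axis of NCHW features."""
    mu = mean(x, axis=1, keepdims=True)
    centered = x - mu
    var = mean(square(centered), axis=1, keepdims=True)
    normed = div(centered, sqrt(add_const(var, eps)))
    return mul(normed, reshape(gain, (1, -1, 1, 1)))


def l2normalize(x: Tensor, axis: int = -1, eps: float = 1e-8) -> Tensor:
    norm = sqrt(add_const(sum_(square(x), axis=axis, keepdims=True), eps))
    return div(x, norm)


def mse(a: Tensor, b: Tensor) -> Tensor:
    return mean(square(a - b))
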