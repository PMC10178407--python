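"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine: each op returns a new :class:`Tensor` holding a
closure that propagates the upstream gradient to its parents.  Only the ops
needed by the segmentation network are provided (elementwise arithmetic with
broadcasting, matmul, conv2d via im2col, average pooling, batch norm,
bilinear resampling, channel softmax, concatenation, axis permutation and
reductions).  Gradients accumulate in ``Tensor.grad`` as plain ndarrays.

Arrays are kept in whatever float dtype they arrive in; the network uses
float32 for speed, while gradient-checking tests use float64.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "avg_pool2d",
    "batch_norm2d",
    "upsample_bilinear",
    "bilinear_matrix",
]


def _as_float(data):
    arr = np.asarray(data)
    if not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float32)
    return arr


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus the backward closure that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_float(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        parents = tuple(p for p in parents if isinstance(p, Tensor))
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd -------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: deep graphs exceed recursion limits
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad):
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other._accum(self.data.swapaxes(-1, -2) @ g)

        return Tensor._make(out_data, (self, other), backward)

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        # clipped for float32 overflow safety; saturates identically
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    # -- reductions / reshaping ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
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

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def permute(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def slice(self, index):
        """Differentiable basic slicing."""
        out_data = self.data[index]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[index] = g
                self._accum(full)

        return Tensor._make(out_data, (self,), backward)

    def softmax(self, axis=1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                dot = (g * p).sum(axis=axis, keepdims=True)
                self._accum(p * (g - dot))

        return Tensor._make(p, (self,), backward)


def concat(tensors, axis=1):
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor._make(out_data, tuple(tensors), backward)


# -- spatial ops ---------------------------------------------------------------


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int):
    """(B,C,Hp,Wp) -> (B,Ho,Wo,C,kh,kw) strided view."""
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (B,C,Ho,Wo,kh,kw)
    return win.transpose(0, 2, 3, 1, 4, 5)


def _col2im(dcols: np.ndarray, shape, kh, kw, stride):
    """Scatter-add (B,Ho,Wo,C,kh,kw) gradients back to a (B,C,Hp,Wp) array."""
    B, C, Hp, Wp = shape
    Ho, Wo = dcols.shape[1], dcols.shape[2]
    dxp = np.zeros(shape, dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride] += (
                dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            )
    return dxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1, padding: int = 0):
    """2-D cross-correlation, NCHW layout, weight (O, C, kh, kw)."""
    B, C, H, W = x.data.shape
    O, Cw, kh, kw = weight.data.shape
    if Cw != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight expects {Cw}")
    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        if padding
        else x.data
    )
    cols = _im2col(xp, kh, kw, stride)  # (B,Ho,Wo,C,kh,kw)
    Ho, Wo = cols.shape[1], cols.shape[2]
    cols2 = np.ascontiguousarray(cols).reshape(B * Ho * Wo, C * kh * kw)
    wmat = weight.data.reshape(O, C * kh * kw)
    out = cols2 @ wmat.T
    if bias is not None:
        out += bias.data
    out_data = out.reshape(B, Ho, Wo, O).transpose(0, 3, 1, 2)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(B * Ho * Wo, O)
        if weight.requires_grad:
            weight._accum((gmat.T @ cols2).reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(gmat.sum(axis=0))
        if x.requires_grad:
            dcols = (gmat @ wmat).reshape(B, Ho, Wo, C, kh, kw)
            dxp = _col2im(dcols, xp.shape, kh, kw, stride)
            if padding:
                dxp = dxp[:, :, padding : padding + H, padding : padding + W]
            x._accum(dxp)

    return Tensor._make(out_data, (x, weight) + ((bias,) if bias is not None else ()), backward)


def avg_pool2d(x: Tensor, kernel: int, stride: int, padding: int = 0):
    """Average pooling, count includes zero padding."""
    B, C, H, W = x.data.shape
    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        if padding
        else x.data
    )
    cols = _im2col(xp, kernel, kernel, stride)  # (B,Ho,Wo,C,k,k)
    out_data = cols.mean(axis=(4, 5)).transpose(0, 3, 1, 2)

    def backward(g):
        if not x.requires_grad:
            return
        B2, C2, Ho, Wo = g.shape
        gexp = np.broadcast_to(
            (g / (kernel * kernel)).transpose(0, 2, 3, 1)[..., None, None],
            (B2, Ho, Wo, C2, kernel, kernel),
        )
        dxp = _col2im(np.ascontiguousarray(gexp), xp.shape, kernel, kernel, stride)
        if padding:
            dxp = dxp[:, :, padding : padding + H, padding : padding + W]
        x._accum(dxp)

    return Tensor._make(out_data, (x,), backward)


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
):
    """Per-channel batch normalisation; updates running stats in place while training."""
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gi = gamma.data[None, :, None, None] * inv[None, :, None, None]
            if training:
                gsum = g.sum(axis=(0, 2, 3))[None, :, None, None]
                gx = (g * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
                dx = gi * (g - gsum / n - xhat * gx / n)
            else:
                dx = gi * g
            x._accum(dx)

    return Tensor._make(out_data, (x, gamma, beta), backward)


def bilinear_matrix(n_out: int, n_in: int, dtype=np.float32) -> np.ndarray:
    """Row-stochastic interpolation matrix mapping length-``n_in`` samples to
    ``n_out``, with half-pixel-centre alignment (identity when sizes match)."""
    if n_out == n_in:
        return np.eye(n_in, dtype=dtype)
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    i0 = np.clip(np.floor(src).astype(int), 0, n_in - 1)
    i1 = np.clip(i0 + 1, 0, n_in - 1)
    frac = np.clip(src - np.floor(src), 0.0, 1.0)
    frac[src < 0] = 0.0
    A = np.zeros((n_out, n_in), dtype=dtype)
    np.add.at(A, (np.arange(n_out), i0), 1.0 - frac)
    np.add.at(A, (np.arange(n_out), i1), frac)
    return A


def upsample_bilinear(x: Tensor, size: tuple[int, int]):
    """Separable bilinear resampling of a NCHW tensor to ``size`` (H, W)."""
    H2, W2 = size
    _, _, H, W = x.data.shape
    Ah = bilinear_matrix(H2, H, dtype=x.data.dtype)
    Aw = bilinear_matrix(W2, W, dtype=x.data.dtype)
    out_data = Ah @ x.data @ Aw.T  # broadcast over leading (B, C)

    def backward(g):
        if x.requires_grad:
            x._accum(Ah.T @ g @ Aw)

    return Tensor._make(out_data, (x,), backward)
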