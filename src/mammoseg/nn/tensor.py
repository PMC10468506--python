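"""Reverse-mode automatic differentiation on NumPy arrays.

A small define-by-run tensor engine: each operation records its parents and a
backward closure; :meth:`Tensor.backward` walks the graph in reverse
topological order accumulating gradients. Data is kept in float32 unless the
caller supplies float64. Only the operations needed by the segmentation
networks are implemented (elementwise arithmetic, matmul, reductions,
reshaping, padding, slicing, rolling, convolution, pooling, upsampling and the
fused activations).
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "Parameter", "concat", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def _as_array(x) -> np.ndarray:
    arr = np.asarray(x)
    if arr.dtype == np.float64 or arr.dtype == np.float32:
        return arr
    return arr.astype(np.float32)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ---------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        req = is_grad_enabled() and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                # free graph references so memory is reclaimed eagerly
                node._backward = None
                node._parents = ()
                node.grad = None  # non-leaf: gradient no longer needed

    def _accum(self, grad: np.ndarray, own: bool = False) -> None:
        """Accumulate a gradient contribution.

        `own=True` promises the array is freshly allocated and not aliased by
        the caller, so it can be adopted without a defensive copy."""
        if self.grad is None:
            if own and grad.dtype == self.data.dtype:
                self.grad = grad
            else:
                self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    # -- basics -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        a, b = self, Tensor._lift(other)
        out_data = a.data + b.data

        def bw(g):
            if a.requires_grad:
                ga = _unbroadcast(g, a.data.shape)
                a._accum(ga, own=ga is not g)
            if b.requires_grad:
                gb = _unbroadcast(g, b.data.shape)
                b._accum(gb, own=gb is not g)

        return Tensor._make(out_data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            a._accum(-g, own=True)

        return Tensor._make(-a.data, (a,), bw)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._lift(other)
        out_data = a.data * b.data

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape), own=True)
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape), own=True)

        return Tensor._make(out_data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        b = Tensor._lift(other)
        return self * b ** -1.0

    def __rtruediv__(self, other):
        return Tensor._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        a = self
        out_data = a.data ** p

        def bw(g):
            a._accum(g * p * a.data ** (p - 1), own=True)

        return Tensor._make(out_data, (a,), bw)

    def __matmul__(self, other):
        a, b = self, Tensor._lift(other)
        out_data = a.data @ b.data

        def bw(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.data.shape), own=True)
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.data.shape), own=True)

        return Tensor._make(out_data, (a, b), bw)

    # -- elementwise functions -------------------------------------------

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bw(g):
            a._accum(g * out_data, own=True)

        return Tensor._make(out_data, (a,), bw)

    def log(self):
        a = self

        def bw(g):
            a._accum(g / a.data, own=True)

        return Tensor._make(np.log(a.data), (a,), bw)

    def relu(self):
        a = self
        mask = a.data > 0

        def bw(g):
            a._accum(g * mask, own=True)

        return Tensor._make(a.data * mask, (a,), bw)

    def leaky_relu(self, slope: float = 0.01):
        a = self
        mult = np.where(a.data > 0, 1.0, slope).astype(a.data.dtype)

        def bw(g):
            a._accum(g * mult, own=True)

        return Tensor._make(a.data * mult, (a,), bw)

    def gelu(self):
        """Exact GELU, x * Phi(x), with the analytic derivative."""
        from scipy.special import erf

        a = self
        x = a.data
        phi_cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
        out_data = (x * phi_cdf).astype(x.dtype)

        def bw(g):
            a._accum(g * (phi_cdf + x * pdf).astype(x.dtype), own=True)

        return Tensor._make(out_data, (a,), bw)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def bw(g):
            a._accum(g * out_data * (1.0 - out_data), own=True)

        return Tensor._make(out_data, (a,), bw)

    # -- reductions -------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape))
            else:
                gg = g
                if not keepdims:
                    gg = np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.data.shape))

        return Tensor._make(out_data, (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation ----------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        orig = a.data.shape

        def bw(g):
            a._accum(g.reshape(orig))

        return Tensor._make(a.data.reshape(shape), (a,), bw)

    def transpose(self, axes: Sequence[int]):
        a = self
        inv = np.argsort(axes)

        def bw(g):
            a._accum(np.transpose(g, inv))

        return Tensor._make(np.ascontiguousarray(np.transpose(a.data, axes)), (a,), bw)

    def pad(self, pad_width):
        """Zero padding; pad_width as for np.pad."""
        a = self
        pw = tuple(tuple(p) for p in pad_width)

        def bw(g):
            sl = tuple(slice(p0, g.shape[i] - p1) for i, (p0, p1) in enumerate(pw))
            a._accum(g[sl])

        return Tensor._make(np.pad(a.data, pw), (a,), bw)

    def __getitem__(self, idx):
        a = self
        out_data = a.data[idx]

        def bw(g):
            full = np.zeros_like(a.data)
            full[idx] = g
            a._accum(full, own=True)

        return Tensor._make(np.ascontiguousarray(out_data), (a,), bw)

    def roll(self, shift: Sequence[int], axis: Sequence[int]):
        a = self
        shift = tuple(shift)
        axis = tuple(axis)

        def bw(g):
            a._accum(np.roll(g, tuple(-s for s in shift), axis), own=True)

        return Tensor._make(np.roll(a.data, shift, axis), (a,), bw)

    # -- fused NN primitives ---------------------------------------------

    def softmax(self, axis: int = -1):
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            a._accum(out_data * (g - dot), own=True)

        return Tensor._make(out_data, (a,), bw)

    def log_softmax(self, axis: int = -1):
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out_data = z - lse
        sm = np.exp(out_data)

        def bw(g):
            a._accum(g - sm * g.sum(axis=axis, keepdims=True), own=True)

        return Tensor._make(out_data, (a,), bw)

    def conv3d(self, weight: "Tensor", bias: "Tensor | None", padding: tuple[int, int, int]):
        """3-D cross-correlation, stride 1.

        self: (N, C, H, W, D); weight: (O, C, kh, kw, kd); padding per axis.
        Implemented by im2col + matmul; the input gradient is the full
        correlation of the output gradient with the flipped kernel, also via
        im2col, so everything runs through BLAS.
        """
        x, w = self, weight
        N, C, H, W, D = x.data.shape
        O, Cw, kh, kw, kd = w.data.shape
        if C != Cw:
            raise ValueError(f"channel mismatch: input {C}, weight {Cw}")
        ph, pw_, pd = padding

        def _cols(arr, pads, ks):
            ap = np.pad(arr, ((0, 0), (0, 0), (pads[0], pads[0]),
                              (pads[1], pads[1]), (pads[2], pads[2])))
            v = sliding_window_view(ap, ks, axis=(2, 3, 4))
            # (N, C, Ho, Wo, Do, kh, kw, kd) -> (N*P, C*K)
            n, c, ho, wo, do = v.shape[:5]
            v = v.transpose(0, 2, 3, 4, 1, 5, 6, 7)
            return v.reshape(n * ho * wo * do, c * ks[0] * ks[1] * ks[2]), (ho, wo, do)

        cols, (Ho, Wo, Do) = _cols(x.data, (ph, pw_, pd), (kh, kw, kd))
        wmat = w.data.reshape(O, -1)
        y = cols @ wmat.T
        if bias is not None:
            y = y + bias.data[None, :]
        out_data = np.ascontiguousarray(
            y.reshape(N, Ho, Wo, Do, O).transpose(0, 4, 1, 2, 3))

        parents = (x, w) if bias is None else (x, w, bias)

        def bw(g):
            gmat = g.transpose(0, 2, 3, 4, 1).reshape(-1, O)
            if w.requires_grad:
                w._accum(np.ascontiguousarray(
                    (gmat.T @ cols).reshape(w.data.shape)), own=True)
            if bias is not None and bias.requires_grad:
                bias._accum(gmat.sum(axis=0), own=True)
            if x.requires_grad:
                # full conv of g with kernel flipped, channels swapped
                gcols, _ = _cols(g, (kh - 1 - ph, kw - 1 - pw_, kd - 1 - pd),
                                 (kh, kw, kd))
                wflip = np.ascontiguousarray(
                    w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
                gx = gcols @ wflip.reshape(C, -1).T
                x._accum(np.ascontiguousarray(
                    gx.reshape(N, H, W, D, C).transpose(0, 4, 1, 2, 3)), own=True)

        return Tensor._make(out_data, parents, bw)

    def maxpool3d(self, stride: tuple[int, int, int]):
        """Non-overlapping max pooling (kernel == stride); dims must divide."""
        a = self
        N, C, H, W, D = a.data.shape
        sh, sw, sd = stride
        if H % sh or W % sw or D % sd:
            raise ValueError(f"shape {(H, W, D)} not divisible by pool stride {stride}")
        v = a.data.reshape(N, C, H // sh, sh, W // sw, sw, D // sd, sd)
        v = v.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
            N, C, H // sh, W // sw, D // sd, sh * sw * sd)
        arg = v.argmax(axis=-1)
        out_data = np.take_along_axis(v, arg[..., None], axis=-1)[..., 0]

        def bw(g):
            gv = np.zeros((N, C, H // sh, W // sw, D // sd, sh * sw * sd),
                          dtype=a.data.dtype)
            np.put_along_axis(gv, arg[..., None], g[..., None], axis=-1)
            gv = gv.reshape(N, C, H // sh, W // sw, D // sd, sh, sw, sd)
            gv = gv.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(N, C, H, W, D)
            a._accum(np.ascontiguousarray(gv), own=True)

        return Tensor._make(np.ascontiguousarray(out_data), (a,), bw)

    def upsample_nearest(self, factors: tuple[int, int, int]):
        a = self
        fh, fw, fd = factors
        out_data = a.data.repeat(fh, axis=2).repeat(fw, axis=3).repeat(fd, axis=4)

        def bw(g):
            N, C, H, W, D = a.data.shape
            gv = g.reshape(N, C, H, fh, W, fw, D, fd)
            a._accum(gv.sum(axis=(3, 5, 7)), own=True)

        return Tensor._make(out_data, (a,), bw)


class Parameter(Tensor):
    """A trainable tensor (requires_grad always True)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = list(tensors)
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offs = np.cumsum([0] + sizes)

    def bw(g):
        for t, o0, o1 in zip(ts, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(int(o0), int(o1))
                t._accum(np.ascontiguousarray(g[tuple(sl)]))

    return Tensor._make(out_data, ts, bw)
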