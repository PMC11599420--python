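"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it on a tape; :meth:`Tensor.backward` walks the tape in reverse topological
order and accumulates gradients.  Only the operations needed by the
translation networks and losses in this package are provided: elementwise
arithmetic, matmul, reductions, reshaping/indexing, 2-D convolution via
im2col, pooling, padding and a numerically stable log-sum-exp.

The engine is deliberately eager and single-threaded apart from BLAS; ops
are coarse (a whole convolution is one tape node) so tape overhead stays
negligible next to the matrix products.
"""

from __future__ import annotations

import numpy as np

_grad_enabled = True


class no_grad:
    """Context manager disabling tape recording (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _sum_to_shape(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    if g.shape == shape:
        return g
    nd_extra = g.ndim - len(shape)
    if nd_extra > 0:
        g = g.sum(axis=tuple(range(nd_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self._backward = None
        self._parents = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
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
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node._backward = None  # free closures eagerly
        return self

    # ---------------------------------------------------------------- helpers
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    @staticmethod
    def _accum(t: "Tensor", g: np.ndarray):
        if not t.requires_grad:
            return
        g = g.astype(t.data.dtype, copy=False)
        if t.grad is None:
            t.grad = g.copy() if g.base is not None or not g.flags.owndata else g
        else:
            t.grad = t.grad + g

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        a, b = self, self._lift(other)

        def bwd(g):
            self._accum(a, _sum_to_shape(g, a.data.shape))
            self._accum(b, _sum_to_shape(g, b.data.shape))

        return self._make(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __mul__(self, other):
        a, b = self, self._lift(other)

        def bwd(g):
            self._accum(a, _sum_to_shape(g * b.data, a.data.shape))
            self._accum(b, _sum_to_shape(g * a.data, b.data.shape))

        return self._make(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __neg__(self):
        a = self

        def bwd(g):
            self._accum(a, -g)

        return self._make(-a.data, (a,), bwd)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        a, b = self, self._lift(other)

        def bwd(g):
            self._accum(a, _sum_to_shape(g / b.data, a.data.shape))
            self._accum(b, _sum_to_shape(-g * a.data / (b.data * b.data), b.data.shape))

        return self._make(a.data / b.data, (a, b), bwd)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def pow(self, p: float):
        a = self
        out_data = a.data ** p

        def bwd(g):
            self._accum(a, g * p * a.data ** (p - 1.0))

        return self._make(out_data, (a,), bwd)

    __pow__ = pow

    def sqrt(self):
        a = self
        r = np.sqrt(a.data)

        def bwd(g):
            self._accum(a, g * 0.5 / r)

        return self._make(r, (a,), bwd)

    def exp(self):
        a = self
        e = np.exp(a.data)

        def bwd(g):
            self._accum(a, g * e)

        return self._make(e, (a,), bwd)

    def log(self):
        a = self

        def bwd(g):
            self._accum(a, g / a.data)

        return self._make(np.log(a.data), (a,), bwd)

    def tanh(self):
        a = self
        t = np.tanh(a.data)

        def bwd(g):
            self._accum(a, g * (1.0 - t * t))

        return self._make(t, (a,), bwd)

    def relu(self):
        a = self
        mask = a.data > 0

        def bwd(g):
            self._accum(a, g * mask)

        return self._make(a.data * mask, (a,), bwd)

    def leaky_relu(self, slope: float = 0.2):
        a = self
        mask = a.data > 0

        def bwd(g):
            self._accum(a, g * np.where(mask, 1.0, slope))

        return self._make(np.where(mask, a.data, a.data * slope), (a,), bwd)

    def softplus(self):
        a = self
        z = a.data
        out = np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0.0)
        sig = 1.0 / (1.0 + np.exp(-z))

        def bwd(g):
            self._accum(a, g * sig)

        return self._make(out, (a,), bwd)

    def clamp_min(self, lo: float):
        a = self
        mask = a.data > lo

        def bwd(g):
            self._accum(a, g * mask)

        return self._make(np.maximum(a.data, lo), (a,), bwd)

    # -------------------------------------------------------------- structure
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        orig = a.data.shape

        def bwd(g):
            self._accum(a, g.reshape(orig))

        return self._make(a.data.reshape(shape), (a,), bwd)

    def transpose(self, *axes):
        a = self
        if not axes:
            axes = tuple(reversed(range(a.data.ndim)))
        inv = np.argsort(axes)

        def bwd(g):
            self._accum(a, g.transpose(inv))

        return self._make(a.data.transpose(axes), (a,), bwd)

    @property
    def T(self):
        return self.transpose()

    def take(self, indices, axis: int):
        """Gather along ``axis`` with integer ``indices`` (scatter-add backward)."""
        a = self
        indices = np.asarray(indices)

        def bwd(g):
            if not a.requires_grad:
                return
            buf = np.zeros_like(a.data)
            idx = [slice(None)] * a.data.ndim
            idx[axis] = indices
            np.add.at(buf, tuple(idx), g)
            self._accum(a, buf)

        return self._make(np.take(a.data, indices, axis=axis), (a,), bwd)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        shape = a.data.shape

        def bwd(g):
            if axis is None:
                self._accum(a, np.broadcast_to(g, shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(a, np.broadcast_to(g, shape).copy())

        return self._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        a = self
        if axis is None:
            n = a.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([a.data.shape[i] for i in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def logsumexp(self, axis: int, keepdims: bool = False):
        a = self
        m = a.data.max(axis=axis, keepdims=True)
        e = np.exp(a.data - m)
        s = e.sum(axis=axis, keepdims=True)
        out = m + np.log(s)
        soft = e / s

        def bwd(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(a, g * soft)

        return self._make(out if keepdims else np.squeeze(out, axis), (a,), bwd)

    # ------------------------------------------------------------ linear alg
    def matmul(self, other):
        a, b = self, self._lift(other)

        def bwd(g):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                self._accum(a, _sum_to_shape(ga, a.data.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                self._accum(b, _sum_to_shape(gb, b.data.shape))

        return self._make(np.matmul(a.data, b.data), (a, b), bwd)

    __matmul__ = matmul


# --------------------------------------------------------------------- ops
def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if _grad_enabled and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(t for t in tensors if t.requires_grad)

        def bwd(g):
            for t, lo, hi in zip(tensors, offs[:-1], offs[1:]):
                if t.requires_grad:
                    idx = [slice(None)] * g.ndim
                    idx[axis] = slice(lo, hi)
                    Tensor._accum(t, g[tuple(idx)])

        out._backward = bwd
    return out


def pad2d(x: Tensor, pad: int, mode: str = "reflect") -> Tensor:
    """Pad the two trailing (spatial) axes of an NCHW tensor."""
    if pad == 0:
        return x
    x = Tensor._lift(x)
    widths = [(0, 0)] * (x.ndim - 2) + [(pad, pad), (pad, pad)]
    if mode == "zeros":
        data = np.pad(x.data, widths)
    else:
        data = np.pad(x.data, widths, mode=mode)
    out = Tensor(data)
    if _grad_enabled and x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)
        H, W = x.data.shape[-2:]

        def bwd(g):
            if mode == "zeros":
                core = g[..., pad:pad + H, pad:pad + W]
            else:
                # fold reflected borders back onto their source pixels
                core = np.zeros_like(x.data)
                np.add.at(
                    core,
                    (Ellipsis,
                     _reflect_index(H, pad)[:, None],
                     _reflect_index(W, pad)[None, :]),
                    g,
                )
                Tensor._accum(x, core)
                return
            Tensor._accum(x, core)

        out._backward = bwd
    return out


def _reflect_index(n: int, pad: int) -> np.ndarray:
    idx = np.arange(-pad, n + pad)
    return np.abs(idx) * (idx < 0) + idx * (idx >= 0) * (idx < n) + \
        (2 * n - 2 - idx) * (idx >= n)


def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    N, C, H, W = x.shape
    Ho = (H - kh) // sh + 1
    Wo = (W - kw) // sw + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, (N, C, kh, kw, Ho, Wo), (s0, s1, s2, s3, s2 * sh, s3 * sw)
    )
    return np.ascontiguousarray(cols).reshape(N, C * kh * kw, Ho * Wo), Ho, Wo


def _col2im(cols: np.ndarray, xshape, kh, kw, sh, sw) -> np.ndarray:
    N, C, H, W = xshape
    Ho = (H - kh) // sh + 1
    Wo = (W - kw) // sw + 1
    cols = cols.reshape(N, C, kh, kw, Ho, Wo)
    gx = np.zeros(xshape, dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            gx[:, :, i:i + Ho * sh:sh, j:j + Wo * sw:sw] += cols[:, :, i, j]
    return gx


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1) -> Tensor:
    """Valid 2-D convolution (cross-correlation), NCHW x OIHW -> NOHW.

    Padding is applied separately via :func:`pad2d` so the core op stays
    'valid'; this keeps reflection padding differentiable.
    """
    x, w = Tensor._lift(x), Tensor._lift(w)
    N = x.data.shape[0]
    O, I, kh, kw = w.data.shape
    cols, Ho, Wo = _im2col(x.data, kh, kw, stride, stride)
    wmat = w.data.reshape(O, I * kh * kw)
    out_data = np.matmul(wmat, cols).reshape(N, O, Ho, Wo)
    if b is not None:
        out_data = out_data + b.data.reshape(1, O, 1, 1)
    parents = [x, w] + ([b] if b is not None else [])
    out = Tensor(out_data)
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)

        def bwd(g):
            gmat = g.reshape(N, O, Ho * Wo)
            if w.requires_grad:
                gw = np.matmul(gmat, cols.transpose(0, 2, 1)).sum(axis=0)
                Tensor._accum(w, gw.reshape(O, I, kh, kw))
            if b is not None and b.requires_grad:
                Tensor._accum(b, g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gcols = np.matmul(wmat.T, gmat)
                Tensor._accum(x, _col2im(gcols, x.data.shape, kh, kw, stride, stride))

        out._backward = bwd
    return out


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping k x k average pooling; spatial dims must divide by k."""
    x = Tensor._lift(x)
    N, C, H, W = x.data.shape
    if H % k or W % k:
        raise ValueError(f"avg_pool2d: spatial dims ({H},{W}) not divisible by {k}")
    r = x.data.reshape(N, C, H // k, k, W // k, k)
    out = Tensor(r.mean(axis=(3, 5)))
    if _grad_enabled and x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)

        def bwd(g):
            gx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
            Tensor._accum(x, gx)

        out._backward = bwd
    return out


def upsample_nearest2d(x: Tensor, k: int = 2) -> Tensor:
    x = Tensor._lift(x)
    out = Tensor(np.repeat(np.repeat(x.data, k, axis=2), k, axis=3))
    if _grad_enabled and x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)
        N, C, H, W = x.data.shape

        def bwd(g):
            gx = g.reshape(N, C, H, k, W, k).sum(axis=(3, 5))
            Tensor._accum(x, gx)

        out._backward = bwd
    return out
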