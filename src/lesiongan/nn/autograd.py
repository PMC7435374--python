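"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the primitives the image-translation networks need:
elementwise arithmetic with broadcasting, reductions, activations,
2-D convolution (via im2col), zero-dilation (for transposed convolution),
padding, cropping, channel concatenation and 2x2 max pooling.

Gradients flow through a dynamically built DAG; :meth:`Tensor.backward`
performs a topological sort and accumulates gradients in float64/float32
matching the data dtype.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # so ndarray.__mul__ defers to us

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64 if not isinstance(data, np.ndarray) else None)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- basic protocol -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    # -- graph traversal ------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise ValueError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise ValueError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs are deep (9 res blocks + VGG)
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
        self.grad = grad.astype(self.data.dtype, copy=True)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return _make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g, a=self):
            a._accum(-g)
        return _make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = self.data * other.data

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return _make(out, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        e = float(exponent)
        out = self.data ** e

        def bwd(g, a=self):
            a._accum(g * e * a.data ** (e - 1.0))

        return _make(out, (self,), bwd)

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g, a=self):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.shape).astype(a.data.dtype))

        return _make(out, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[i] for i in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- activations ----------------------------------------------------
    def relu(self):
        mask = self.data > 0
        def bwd(g, a=self):
            a._accum(g * mask)
        return _make(self.data * mask, (self,), bwd)

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        factor = np.where(mask, 1.0, slope)
        def bwd(g, a=self):
            a._accum(g * factor)
        return _make(self.data * factor, (self,), bwd)

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        def bwd(g, a=self):
            a._accum(g * out * (1.0 - out))
        return _make(out, (self,), bwd)

    def abs(self):
        sign = np.sign(self.data)
        def bwd(g, a=self):
            a._accum(g * sign)
        return _make(np.abs(self.data), (self,), bwd)

    def sqrt(self):
        return self ** 0.5

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        old = self.shape
        def bwd(g, a=self):
            a._accum(g.reshape(old))
        return _make(self.data.reshape(*shape), (self,), bwd)

    def swapaxes(self, a1: int, a2: int):
        def bwd(g, a=self):
            a._accum(g.swapaxes(a1, a2))
        return _make(self.data.swapaxes(a1, a2), (self,), bwd)

    def flip_spatial(self):
        """Flip the last two axes (kernel rotation for transposed conv)."""
        def bwd(g, a=self):
            a._accum(g[..., ::-1, ::-1])
        return _make(self.data[..., ::-1, ::-1].copy(), (self,), bwd)

    def crop2d(self, top: int, left: int, height: int, width: int):
        """Take a spatial window of an (N, C, H, W) tensor."""
        sl = (slice(None), slice(None), slice(top, top + height), slice(left, left + width))
        def bwd(g, a=self):
            full = np.zeros_like(a.data)
            full[sl] = g
            a._accum(full)
        return _make(self.data[sl].copy(), (self,), bwd)

    def pad2d(self, pt: int, pb: int, pl: int, pr: int):
        """Zero-pad the last two axes of an (N, C, H, W) tensor."""
        widths = ((0, 0),) * (self.ndim - 2) + ((pt, pb), (pl, pr))
        out = np.pad(self.data, widths)
        def bwd(g, a=self):
            sl = (Ellipsis, slice(pt, g.shape[-2] - pb), slice(pl, g.shape[-1] - pr))
            a._accum(g[sl])
        return _make(out, (self,), bwd)

    def dilate2d(self, stride: int):
        """Insert `stride-1` zeros between spatial elements (transposed-conv upsampling)."""
        if stride == 1:
            return self
        n, c, h, w = self.shape
        out = np.zeros((n, c, (h - 1) * stride + 1, (w - 1) * stride + 1), dtype=self.data.dtype)
        out[:, :, ::stride, ::stride] = self.data
        def bwd(g, a=self):
            a._accum(g[:, :, ::stride, ::stride])
        return _make(out, (self,), bwd)

    # -- convolution ------------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0):
        """Cross-correlation of (N, C, H, W) with weight (OC, C, kh, kw)."""
        x = self.pad2d(padding, padding, padding, padding) if padding else self
        xd = x.data
        n, c, h, w = xd.shape
        oc, wc, kh, kw = weight.shape
        if wc != c:
            raise ValueError(f"conv2d channel mismatch: input {c}, weight expects {wc}")
        if h < kh or w < kw:
            raise ValueError(f"conv2d input {h}x{w} smaller than kernel {kh}x{kw}")
        oh = (h - kh) // stride + 1
        ow = (w - kw) // stride + 1
        s0, s1, s2, s3 = xd.strides
        cols = np.lib.stride_tricks.as_strided(
            xd, (n, c, kh, kw, oh, ow), (s0, s1, s2, s3, s2 * stride, s3 * stride)
        ).reshape(n, c * kh * kw, oh * ow)
        wmat = weight.data.reshape(oc, c * kh * kw)
        out = np.einsum("ok,nkp->nop", wmat, cols, optimize=True).reshape(n, oc, oh, ow)
        if bias is not None:
            out = out + bias.data.reshape(1, oc, 1, 1)

        def bwd(g, a=x, wt=weight, bt=bias):
            gm = g.reshape(n, oc, oh * ow)
            if wt.requires_grad:
                gw = np.einsum("nop,nkp->ok", gm, cols, optimize=True)
                wt._accum(gw.reshape(wt.shape))
            if bt is not None and bt.requires_grad:
                bt._accum(g.sum(axis=(0, 2, 3)))
            if a.requires_grad:
                dcols = np.einsum("ok,nop->nkp", wmat, gm, optimize=True)
                dcols = dcols.reshape(n, c, kh, kw, oh, ow)
                dx = np.zeros_like(xd)
                for i in range(kh):
                    for j in range(kw):
                        dx[:, :, i:i + oh * stride:stride, j:j + ow * stride:stride] += dcols[:, :, i, j]
                a._accum(dx)

        parents = (x, weight) if bias is None else (x, weight, bias)
        return _make(out, parents, bwd)

    def max_pool2x2(self):
        """2x2 max pooling with stride 2 on an (N, C, H, W) tensor."""
        n, c, h, w = self.shape
        h2, w2 = h // 2, w // 2
        win = self.data[:, :, :h2 * 2, :w2 * 2].reshape(n, c, h2, 2, w2, 2)
        win = win.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        idx = win.argmax(axis=-1)
        out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

        def bwd(g, a=self):
            dwin = np.zeros((n, c, h2, w2, 4), dtype=a.data.dtype)
            np.put_along_axis(dwin, idx[..., None], g[..., None], axis=-1)
            dwin = dwin.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            dx = np.zeros_like(a.data)
            dx[:, :, :h2 * 2, :w2 * 2] = dwin.reshape(n, c, h2 * 2, w2 * 2)
            a._accum(dx)

        return _make(out, (self,), bwd)


def _make(data: np.ndarray, parents: tuple, bwd) -> Tensor:
    t = Tensor(data, parents=parents)
    if t.requires_grad:
        t._backward = bwd
    return t


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along `axis` (channel concat of image and label stacks)."""
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(int(lo), int(hi))
                t._accum(g[tuple(sl)])

    return _make(out, tuple(tensors), bwd)
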