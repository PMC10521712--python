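"""A compact reverse-mode automatic differentiation engine on numpy arrays.

The engine provides exactly the operator set the segmentation networks in
this package need: broadcasting arithmetic, matmul, reductions, shape
manipulation, zero/replicate padding, channel concatenation/slicing,
2-D convolution (via im2col), 2x2 max pooling, bilinear resizing and a
stride-1 box (sliding-window) mean.  All arrays are float64 and all
operations are deterministic, so identical seeds give bit-identical runs.

Layout convention for feature maps is NCHW (batch, channel, row, col).
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
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
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward = backward

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor through the recorded graph."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative topo sort; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(-g)
        out._backward = bwd
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data,
                     self.requires_grad or other.requires_grad,
                     parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data ** 2, other.shape))
        out._backward = bwd
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))
        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other._accumulate(self.data.swapaxes(-1, -2) @ g)
        out._backward = bwd
        return out

    # -- elementwise nonlinearities --------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, self.requires_grad, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * val)
        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g / self.data)
        out._backward = bwd
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0.0), self.requires_grad,
                     parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * mask)
        out._backward = bwd
        return out

    def sigmoid(self):
        val = 0.5 * (1.0 + np.tanh(0.5 * self.data))  # numerically stable
        out = Tensor(val, self.requires_grad, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * val * (1.0 - val))
        out._backward = bwd
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only through the interior."""
        mask = (self.data > lo) & (self.data < hi)
        out = Tensor(np.clip(self.data, lo, hi), self.requires_grad,
                     parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * mask)
        out._backward = bwd
        return out

    # -- reductions and shape --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad,
                     parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))
        out._backward = bwd
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(axes), self.requires_grad,
                     parents=(self,))
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))
        out._backward = bwd
        return out

    def narrow(self, axis: int, start: int, length: int):
        """Contiguous slice along one axis."""
        idx = [slice(None)] * self.ndim
        idx[axis] = slice(start, start + length)
        idx = tuple(idx)
        out = Tensor(self.data[idx], self.requires_grad, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[idx] = g
                self._accumulate(full)
        out._backward = bwd
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), parents=tensors)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])
    out._backward = bwd
    return out


def pad2d(x: Tensor, pad: tuple[int, int, int, int], mode: str = "zero") -> Tensor:
    """Pad the last two axes by (top, bottom, left, right)."""
    t, b, l, r = pad
    widths = [(0, 0)] * (x.ndim - 2) + [(t, b), (l, r)]
    np_mode = {"zero": "constant", "replicate": "edge"}[mode]
    out = Tensor(np.pad(x.data, widths, mode=np_mode), x.requires_grad,
                 parents=(x,))
    H, W = x.shape[-2], x.shape[-1]

    def bwd(g):
        if not x.requires_grad:
            return
        if mode == "zero":
            x._accumulate(g[..., t:t + H, l:l + W])
        else:  # replicate: edge gradients fold back onto the border cells
            core = g.copy()
            if t:
                core[..., t, :] += core[..., :t, :].sum(axis=-2)
            if b:
                core[..., t + H - 1, :] += core[..., t + H:, :].sum(axis=-2)
            core = core[..., t:t + H, :]
            if l:
                core[..., l] += core[..., :l].sum(axis=-1)
            if r:
                core[..., l + W - 1] += core[..., l + W:].sum(axis=-1)
            x._accumulate(core[..., l:l + W])
    out._backward = bwd
    return out


def _windows(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    # (N, C, H, W) -> view (N, C, H', W', kh, kw), no copy
    return np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           padding: int = 0) -> Tensor:
    """Stride-1 2-D cross-correlation, NCHW, weight (out_c, in_c, kh, kw)."""
    oc, ic, kh, kw = weight.shape
    if x.shape[1] != ic:
        raise ValueError(f"conv2d: input has {x.shape[1]} channels, "
                         f"weight expects {ic}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding),
                         (padding, padding))) if padding else x.data
    win = _windows(xp, kh, kw)
    val = np.einsum("nchwij,ocij->nohw", win, weight.data, optimize=True)
    if bias is not None:
        val += bias.data[None, :, None, None]
    parents = (x, weight) + ((bias,) if bias is not None else ())
    out = Tensor(val, any(p.requires_grad for p in parents), parents=parents)
    h, w = x.shape[2], x.shape[3]

    def bwd(g):
        if weight.requires_grad:
            weight._accumulate(
                np.einsum("nohw,nchwij->ocij", g, win, optimize=True))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # full correlation of the output grad with the flipped kernel
            gp = np.pad(g, ((0, 0), (0, 0), (kh - 1, kh - 1),
                            (kw - 1, kw - 1)))
            gwin = _windows(gp, kh, kw)
            wf = weight.data[:, :, ::-1, ::-1]
            gx = np.einsum("nohwij,ocij->nchw", gwin, wf, optimize=True)
            if padding:
                gx = gx[:, :, padding:padding + h, padding:padding + w]
            x._accumulate(gx)
    out._backward = bwd
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 requires even spatial dims")
    r = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    flat = r.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    arg = flat.argmax(axis=-1)
    val = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    out = Tensor(val, x.requires_grad, parents=(x,))

    def bwd(g):
        if not x.requires_grad:
            return
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, arg[..., None], g[..., None], axis=-1)
        gx = gflat.reshape(n, c, h // 2, w // 2, 2, 2) \
                  .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        x._accumulate(gx)
    out._backward = bwd
    return out


def _linear_resize_coeffs(n_in: int, n_out: int):
    # half-pixel-centre sampling; returns (idx0, idx1, w1) per output position
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = src - i0
    return i0, i1, w1


def resize_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize of the last two axes (half-pixel centres)."""
    n, c, h, w = x.shape
    r0, r1, wr = _linear_resize_coeffs(h, out_h)
    c0, c1, wc = _linear_resize_coeffs(w, out_w)
    wr = wr[:, None]
    top = x.data[:, :, r0, :] * (1 - wr) + x.data[:, :, r1, :] * wr
    val = top[:, :, :, c0] * (1 - wc) + top[:, :, :, c1] * wc
    out = Tensor(val, x.requires_grad, parents=(x,))

    def bwd(g):
        if not x.requires_grad:
            return
        gtop = np.zeros((n, c, out_h, w))
        np.add.at(gtop, (slice(None), slice(None), slice(None), c0),
                  g * (1 - wc))
        np.add.at(gtop, (slice(None), slice(None), slice(None), c1), g * wc)
        gx = np.zeros((n, c, h, w))
        np.add.at(gx, (slice(None), slice(None), r0), gtop * (1 - wr))
        np.add.at(gx, (slice(None), slice(None), r1), gtop * wr)
        x._accumulate(gx)
    out._backward = bwd
    return out


def box_mean(x: Tensor, sh: int, sw: int, stride: int = 1) -> Tensor:
    """Sliding-window mean over sh x sw windows of the last two axes."""
    n, c, h, w = x.shape
    if sh > h or sw > w:
        raise ValueError("box_mean window larger than input")
    win = np.lib.stride_tricks.sliding_window_view(x.data, (sh, sw),
                                                   axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    val = win.mean(axis=(-2, -1))
    out = Tensor(val, x.requires_grad, parents=(x,))
    ho, wo = val.shape[2], val.shape[3]

    def bwd(g):
        if not x.requires_grad:
            return
        gx = np.zeros((n, c, h, w))
        scale = 1.0 / (sh * sw)
        for i in range(sh):
            for j in range(sw):
                gx[:, :, i:i + (ho - 1) * stride + 1:stride,
                   j:j + (wo - 1) * stride + 1:stride] += g * scale
        x._accumulate(gx)
    out._backward = bwd
    return out
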