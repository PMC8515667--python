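"""Reverse-mode autodiff tensor with the ops the networks require.

Images are (C, H, W); there is no batch axis (training uses batch
size 1).  The tape is built eagerly; ``Tensor.backward()`` runs a
topological sweep.  Dtypes are preserved, so float64 can be used for
finite-difference gradient checks while training runs in float32.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "pad2d",
    "conv2d",
    "conv_transpose2d",
    "instance_norm",
    "channel_softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        t = Tensor(data)
        if any(p.requires_grad for p in parents):
            t.requires_grad = True
            t._parents = tuple(parents)
            t._backward = backward
        return t

    def _accum(self, grad):
        grad = np.asarray(grad, dtype=self.data.dtype)
        if self.grad is None:
            self.grad = grad.copy() if grad.base is not None else grad
        else:
            self.grad += grad

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autodiff driver ------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
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
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic -----------------------------------------
    @staticmethod
    def _coerce(x):
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def __add__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    def square(self):
        return self * self

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape))

        return Tensor._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # -- nonlinearities --------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(out_data, (self,), bwd)

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        out_data = np.where(mask, self.data, slope * self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * np.where(mask, 1.0, slope))

        return Tensor._make(out_data, (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), bwd)

    def abs(self):
        sign = np.sign(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * sign)

        return Tensor._make(np.abs(self.data), (self,), bwd)

    # -- shaping ---------------------------------------------------------
    def channels(self, start: int, stop: int) -> "Tensor":
        """View of channels [start, stop) of a (C, H, W) tensor."""
        out_data = self.data[start:stop]

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[start:stop] = g
                self._accum(full)

        return Tensor._make(out_data, (self,), bwd)

    def reshape(self, *shape):
        orig = self.shape
        out_data = self.data.reshape(*shape)

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return Tensor._make(out_data, (self,), bwd)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


# ---------------------------------------------------------------------------
# padding


def pad2d(x: Tensor, pad: int, mode: str = "zero") -> Tensor:
    """Pad the trailing two axes of a (C, H, W) tensor."""
    if pad == 0:
        return x
    C, H, W = x.shape
    widths = ((0, 0), (pad, pad), (pad, pad))
    if mode == "zero":
        out_data = np.pad(x.data, widths)

        def bwd(g):
            if x.requires_grad:
                x._accum(g[:, pad:-pad, pad:-pad])

        return Tensor._make(out_data, (x,), bwd)
    if mode == "reflect":
        out_data = np.pad(x.data, widths, mode="reflect")
        # index maps: padded position -> source position
        ih = np.pad(np.arange(H), (pad, pad), mode="reflect")
        iw = np.pad(np.arange(W), (pad, pad), mode="reflect")

        def bwd(g):
            if not x.requires_grad:
                return
            acc = np.zeros_like(x.data)
            # fold rows then columns back onto their source positions
            tmp = np.zeros((C, H, W + 2 * pad), dtype=g.dtype)
            np.add.at(tmp, (slice(None), ih, slice(None)), g)
            np.add.at(acc, (slice(None), slice(None), iw), tmp)
            x._accum(acc)

        return Tensor._make(out_data, (x,), bwd)
    raise ValueError(f"unknown pad mode {mode!r}")


# ---------------------------------------------------------------------------
# convolution (im2col)


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int):
    """(C, Hp, Wp) -> cols (C*kh*kw, Ho*Wo) plus output shape."""
    C, Hp, Wp = xp.shape
    Ho = (Hp - kh) // stride + 1
    Wo = (Wp - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    win = win[:, ::stride, ::stride]  # (C, Ho, Wo, kh, kw)
    cols = win.transpose(0, 3, 4, 1, 2).reshape(C * kh * kw, Ho * Wo)
    return np.ascontiguousarray(cols), Ho, Wo


def _col2im(dcols: np.ndarray, C: int, Hp: int, Wp: int, kh: int, kw: int,
            stride: int, Ho: int, Wo: int) -> np.ndarray:
    dx = np.zeros((C, Hp, Wp), dtype=dcols.dtype)
    d = dcols.reshape(C, kh, kw, Ho, Wo)
    for i in range(kh):
        for j in range(kw):
            dx[:, i : i + stride * Ho : stride, j : j + stride * Wo : stride] += d[:, i, j]
    return dx


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0, pad_mode: str = "zero") -> Tensor:
    """2-D convolution (cross-correlation) on a (C, H, W) tensor.

    ``w`` is (Cout, Cin, kh, kw); ``b`` is (Cout,) or None.
    """
    xp = pad2d(x, padding, pad_mode) if padding else x
    Cout, Cin, kh, kw = w.shape
    C, Hp, Wp = xp.shape
    if C != Cin:
        raise ValueError(f"input has {C} channels, weight expects {Cin}")
    cols, Ho, Wo = _im2col(xp.data, kh, kw, stride)
    wmat = w.data.reshape(Cout, Cin * kh * kw)
    out_data = (wmat @ cols).reshape(Cout, Ho, Wo)
    if b is not None:
        out_data = out_data + b.data.reshape(Cout, 1, 1)

    parents = (xp, w) if b is None else (xp, w, b)

    def bwd(g):
        gf = g.reshape(Cout, Ho * Wo)
        if b is not None and b.requires_grad:
            b._accum(gf.sum(axis=1))
        if w.requires_grad:
            w._accum((gf @ cols.T).reshape(w.shape))
        if xp.requires_grad:
            dcols = wmat.T @ gf
            xp._accum(_col2im(dcols, Cin, Hp, Wp, kh, kw, stride, Ho, Wo))

    return Tensor._make(out_data, parents, bwd)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 2, padding: int = 1,
                     output_padding: int = 1) -> Tensor:
    """Transposed convolution; ``w`` is (Cin, Cout, kh, kw).

    Output size per axis: ``(H - 1)*stride - 2*padding + k + output_padding``
    (the stride-2, k=3, padding=1, output_padding=1 configuration doubles
    the resolution exactly).
    """
    Cin, Cout, kh, kw = w.shape
    C, H, W = x.shape
    if C != Cin:
        raise ValueError(f"input has {C} channels, weight expects {Cin}")
    Hf = (H - 1) * stride + kh + output_padding
    Wf = (W - 1) * stride + kw + output_padding
    Ho = (H - 1) * stride - 2 * padding + kh + output_padding
    Wo = (W - 1) * stride - 2 * padding + kw + output_padding
    wmat = w.data.reshape(Cin, Cout * kh * kw)
    dcols = wmat.T @ x.data.reshape(Cin, H * W)  # (Cout*kh*kw, H*W)
    full = _col2im(dcols, Cout, Hf, Wf, kh, kw, stride, H, W)
    out_data = full[:, padding : padding + Ho, padding : padding + Wo]
    out_data = np.ascontiguousarray(out_data)
    if b is not None:
        out_data = out_data + b.data.reshape(Cout, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        if b is not None and b.requires_grad:
            b._accum(g.reshape(Cout, -1).sum(axis=1))
        gfull = np.zeros((Cout, Hf, Wf), dtype=g.dtype)
        gfull[:, padding : padding + Ho, padding : padding + Wo] = g
        gcols, nh, nw = _im2col(gfull, kh, kw, stride)
        if (nh, nw) != (H, W):
            # output_padding can add spurious trailing windows; drop them
            gc = gcols.reshape(Cout * kh * kw, nh, nw)[:, :H, :W]
            gcols = np.ascontiguousarray(gc).reshape(Cout * kh * kw, H * W)
        if w.requires_grad:
            w._accum((x.data.reshape(Cin, H * W) @ gcols.T).reshape(w.shape))
        if x.requires_grad:
            x._accum((wmat @ gcols).reshape(Cin, H, W))

    return Tensor._make(out_data, parents, bwd)


# ---------------------------------------------------------------------------
# normalization / softmax


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel normalization over the spatial axes of (C, H, W)."""
    C, H, W = x.shape
    n = H * W
    mu = x.data.mean(axis=(1, 2), keepdims=True)
    xc = x.data - mu
    var = (xc**2).mean(axis=(1, 2), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = gamma.data.reshape(C, 1, 1) * xhat + beta.data.reshape(C, 1, 1)

    def bwd(g):
        if beta.requires_grad:
            beta._accum(g.sum(axis=(1, 2)))
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(1, 2)))
        if x.requires_grad:
            gh = g * gamma.data.reshape(C, 1, 1)
            t1 = gh.sum(axis=(1, 2), keepdims=True)
            t2 = (gh * xhat).sum(axis=(1, 2), keepdims=True)
            x._accum(inv * (gh - t1 / n - xhat * t2 / n))

    return Tensor._make(out_data, (x, gamma, beta), bwd)


def channel_softmax(x: Tensor) -> Tensor:
    """Softmax over the channel axis of (C, H, W), max-stabilized.

    Per pixel, channel i receives exp(a_i) / sum_c exp(a_c); the result
    is non-negative and sums to one over channels.
    """
    z = x.data - x.data.max(axis=0, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=0, keepdims=True)

    def bwd(g):
        if x.requires_grad:
            dot = (g * out_data).sum(axis=0, keepdims=True)
            x._accum(out_data * (g - dot))

    return Tensor._make(out_data, (x,), bwd)
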