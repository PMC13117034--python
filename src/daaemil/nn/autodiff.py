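"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine covering exactly the operations the attention-MIL
models in this package need: broadcasting arithmetic, 2-D matrix products,
elementwise nonlinearities, reductions, reshapes, row gathering,
concatenation, 3-D convolution and average pooling.  Everything is float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv3d", "avg_pool3d", "softmax", "bce_with_logits"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading dims added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._prev: tuple = ()

    # -- bookkeeping -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- op construction helper -------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)

        def bw(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accumulate(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)

        def bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._coerce(other) * self ** -1.0

    def __pow__(self, n: float):
        out_data = self.data ** n

        def bw(g):
            self._accumulate(g * n * self.data ** (n - 1))

        return self._make(out_data, (self,), bw)

    def __matmul__(self, other):
        other = self._coerce(other)
        if self.data.ndim != 2 or other.data.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")

        def bw(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), bw)

    # -- nonlinearities ----------------------------------------------------
    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            self._accumulate(g * (1.0 - out_data ** 2))

        return self._make(out_data, (self,), bw)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def bw(g):
            self._accumulate(g * (self.data > 0.0))

        return self._make(out_data, (self,), bw)

    def sigmoid(self):
        out_data = np.empty_like(self.data)
        pos = self.data >= 0
        out_data[pos] = 1.0 / (1.0 + np.exp(-self.data[pos]))
        ex = np.exp(self.data[~pos])
        out_data[~pos] = ex / (1.0 + ex)

        def bw(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accumulate(g * out_data)

        return self._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accumulate(g / self.data)

        return self._make(np.log(self.data), (self,), bw)

    # -- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        elif isinstance(axis, tuple):
            n = int(np.prod([self.data.shape[a] for a in axis]))
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape

        def bw(g):
            self._accumulate(g.reshape(orig))

        return self._make(self.data.reshape(shape), (self,), bw)

    @property
    def T(self):
        def bw(g):
            self._accumulate(g.T)

        return self._make(self.data.T, (self,), bw)

    def gather_rows(self, idx):
        """Select rows by integer index; gradient scatter-adds back."""
        idx = np.asarray(idx, dtype=np.intp)

        def bw(g):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.add.at(acc, idx, g)
                self._accumulate(acc)

        return self._make(self.data[idx], (self,), bw)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tuple(tensors), bw)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax built from primitive ops."""
    shift = Tensor(t.data.max(axis=axis, keepdims=True))  # constant w.r.t. grad
    e = (t - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def conv3d(x: Tensor, w: Tensor, b: Tensor, padding: int = 1) -> Tensor:
    """'Same'-style 3-D convolution.

    x: (B, Cin, H, W, D); w: (Cout, Cin, k, k, k); b: (Cout,).
    Output spatial size is H+2p-k+1 per axis.
    """
    B, cin, H, W, D = x.data.shape
    cout, cin2, k1, k2, k3 = w.data.shape
    if cin != cin2:
        raise ValueError("channel mismatch between input and kernel")
    p = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    oh, ow, od = H + 2 * p - k1 + 1, W + 2 * p - k2 + 1, D + 2 * p - k3 + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k1, k2, k3), axis=(2, 3, 4))
    # win: (B, Cin, oh, ow, od, k1, k2, k3)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
        B * oh * ow * od, cin * k1 * k2 * k3)
    wmat = w.data.reshape(cout, -1)
    out_data = (cols @ wmat.T + b.data).reshape(B, oh, ow, od, cout)
    out_data = np.ascontiguousarray(out_data.transpose(0, 4, 1, 2, 3))

    def bw(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1)).reshape(-1, cout)
        if w.requires_grad:
            w._accumulate((g2.T @ cols).reshape(w.data.shape))
        if b.requires_grad:
            b._accumulate(g2.sum(axis=0))
        if x.requires_grad:
            dcols = (g2 @ wmat).reshape(B, oh, ow, od, cin, k1, k2, k3)
            dcols = dcols.transpose(0, 4, 1, 2, 3, 5, 6, 7)
            dxp = np.zeros_like(xp)
            for i in range(k1):
                for j in range(k2):
                    for l in range(k3):
                        dxp[:, :, i:i + oh, j:j + ow, l:l + od] += dcols[..., i, j, l]
            x._accumulate(dxp[:, :, p:p + H, p:p + W, p:p + D])

    return Tensor._make(out_data, (x, w, b), bw)


def avg_pool3d(x: Tensor, factors) -> Tensor:
    """Average pooling with per-axis integer factors (fh, fw, fd).

    Trailing positions that do not fill a complete window are dropped.
    """
    fh, fw, fd = factors
    B, C, H, W, D = x.data.shape
    nh, nw, nd = H // fh, W // fw, D // fd
    if min(nh, nw, nd) < 1:
        raise ValueError("pooling factor exceeds input size")
    crop = x.data[:, :, :nh * fh, :nw * fw, :nd * fd]
    out_data = crop.reshape(B, C, nh, fh, nw, fw, nd, fd).mean(axis=(3, 5, 7))

    def bw(g):
        if not x.requires_grad:
            return
        scale = 1.0 / (fh * fw * fd)
        gg = np.broadcast_to(
            g[:, :, :, None, :, None, :, None],
            (B, C, nh, fh, nw, fw, nd, fd)) * scale
        acc = np.zeros_like(x.data)
        acc[:, :, :nh * fh, :nw * fw, :nd * fd] = gg.reshape(
            B, C, nh * fh, nw * fw, nd * fd)
        x._accumulate(acc)

    return Tensor._make(out_data, (x,), bw)


def bce_with_logits(logit: Tensor, target) -> Tensor:
    """Numerically stable binary cross-entropy on logits (elementwise)."""
    x = logit.data
    t = np.asarray(target, dtype=np.float64)
    val = np.maximum(x, 0.0) - x * t + np.log1p(np.exp(-np.abs(x)))
    sig = np.empty_like(x)
    pos = x >= 0
    sig[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    sig[~pos] = ex / (1.0 + ex)

    def bw(g):
        logit._accumulate(g * (sig - t))

    return Tensor._make(val, (logit,), bw)
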