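"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The package trains its networks with plain NumPy, so this module provides
the small set of differentiable primitives the model needs: broadcasting
arithmetic, reductions, two-operand ``einsum``, 2-D convolution (NHWC,
``same``/``valid`` padding) and max-pooling.  Gradients are accumulated by
reverse topological traversal of the recorded graph.

Every public helper (``exp``, ``sum`` ...) dispatches on its argument: given
a plain ``ndarray`` it computes with NumPy and returns an ``ndarray``; given
a :class:`Tensor` it records the operation.  Numerical code elsewhere in the
package (e.g. the capsule mathematics) is therefore written once and runs
both as plain array math and inside the training graph.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "is_tensor",
    "asarray",
    "exp",
    "log",
    "sqrt",
    "relu",
    "sum",
    "mean",
    "softmax",
    "reshape",
    "transpose",
    "einsum",
    "conv2d",
    "maxpool2d",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
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
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph traversal -----------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy() if isinstance(grad, np.ndarray) else np.asarray(grad)
        else:
            self.grad = self.grad + grad

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_wrap(other))

    def __rsub__(self, other):
        return add(_wrap(other), -self)

    def __truediv__(self, other):
        return mul(self, power(_wrap(other), -1.0))

    def __rtruediv__(self, other):
        return mul(_wrap(other), power(self, -1.0))

    def __pow__(self, p):
        return power(self, p)


def is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def asarray(x) -> np.ndarray:
    """The underlying ndarray of ``x`` (pass-through for plain arrays)."""
    return x.data if isinstance(x, Tensor) else np.asarray(x)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _any_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


# ---------------------------------------------------------------------
# elementwise / broadcasting primitives
# ---------------------------------------------------------------------

def _is_scalar(x) -> bool:
    return isinstance(x, (int, float, np.floating, np.integer))


def add(a, b):
    if not _any_tensor(a, b):
        return np.add(a, b)
    if _is_scalar(a):
        a, b = b, a
    if _is_scalar(b):  # python-scalar fast path: keeps float32 graphs float32
        a = _wrap(a)
        out = Tensor(a.data + b, parents=(a,))

        def backward_s(g):
            if a.requires_grad:
                a._accumulate(g)

        out._backward = backward_s
        return out
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    out._backward = backward
    return out


def mul(a, b):
    if not _any_tensor(a, b):
        return np.multiply(a, b)
    if _is_scalar(a):
        a, b = b, a
    if _is_scalar(b):
        a = _wrap(a)
        out = Tensor(a.data * b, parents=(a,))

        def backward_s(g):
            if a.requires_grad:
                a._accumulate(g * b)

        out._backward = backward_s
        return out
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data * b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._backward = backward
    return out


def power(a, p: float):
    if not _any_tensor(a):
        return np.power(a, p)
    a = _wrap(a)
    out = Tensor(np.power(a.data, p), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (p * np.power(a.data, p - 1)))

    out._backward = backward
    return out


def exp(a):
    if not _any_tensor(a):
        return np.exp(a)
    a = _wrap(a)
    out = Tensor(np.exp(a.data), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * out.data)

    out._backward = backward
    return out


def log(a):
    if not _any_tensor(a):
        return np.log(a)
    a = _wrap(a)
    out = Tensor(np.log(a.data), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g / a.data)

    out._backward = backward
    return out


def sqrt(a):
    return power(a, 0.5)


def relu(a):
    if not _any_tensor(a):
        return np.maximum(a, 0)
    a = _wrap(a)
    out = Tensor(np.maximum(a.data, 0), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (a.data > 0))

    out._backward = backward
    return out


# ---------------------------------------------------------------------
# reductions and shape ops
# ---------------------------------------------------------------------

def sum(a, axis=None, keepdims: bool = False):  # noqa: A001 - mirrors np.sum
    if not _any_tensor(a):
        return np.sum(a, axis=axis, keepdims=keepdims)
    a = _wrap(a)
    out = Tensor(np.sum(a.data, axis=axis, keepdims=keepdims), parents=(a,))

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    out._backward = backward
    return out


def mean(a, axis=None, keepdims: bool = False):
    a_arr = asarray(a)
    if axis is None:
        n = a_arr.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a_arr.shape[i] for i in axes]))
    return mul(sum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape):
    if not _any_tensor(a):
        return np.reshape(a, shape)
    a = _wrap(a)
    out = Tensor(a.data.reshape(shape), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.data.shape))

    out._backward = backward
    return out


def transpose(a, axes):
    if not _any_tensor(a):
        return np.transpose(a, axes)
    a = _wrap(a)
    inv = np.argsort(axes)
    out = Tensor(np.transpose(a.data, axes), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.transpose(g, inv))

    out._backward = backward
    return out


def softmax(a, axis: int = -1):
    """Numerically stable softmax along ``axis`` (max-shift is a constant)."""
    shift = np.max(asarray(a), axis=axis, keepdims=True)
    e = exp(add(a, -shift))
    return mul(e, power(sum(e, axis=axis, keepdims=True), -1.0))


def einsum(subscripts: str, a, b):
    """Two-operand einsum.

    Restriction (checked): every index of each operand must appear in the
    output or in the other operand, so each operand gradient is itself a
    single einsum with permuted subscripts.
    """
    ins, out_sub = subscripts.replace(" ", "").split("->")
    a_sub, b_sub = ins.split(",")
    for sub, other in ((a_sub, b_sub), (b_sub, a_sub)):
        missing = set(sub) - set(out_sub) - set(other)
        if missing:
            raise ValueError(f"einsum {subscripts!r}: indices {missing} not recoverable")
    if not _any_tensor(a, b):
        return np.einsum(subscripts, a, b)
    a, b = _wrap(a), _wrap(b)
    out = Tensor(np.einsum(subscripts, a.data, b.data), parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.einsum(f"{out_sub},{b_sub}->{a_sub}", g, b.data))
        if b.requires_grad:
            b._accumulate(np.einsum(f"{out_sub},{a_sub}->{b_sub}", g, a.data))

    out._backward = backward
    return out


# ---------------------------------------------------------------------
# spatial primitives (NHWC)
# ---------------------------------------------------------------------

def _same_pad(n: int, m: int, s: int) -> tuple[int, int]:
    """'same' padding amounts (before, after): output ceil(n/s), extra pad after."""
    out = -(-n // s)
    total = max((out - 1) * s + m - n, 0)
    return total // 2, total - total // 2


def _out_size(n: int, m: int, s: int, padding: str) -> int:
    if padding == "same":
        return -(-n // s)
    return (n - m) // s + 1


def _im2col(xp: np.ndarray, m: int, s: int, oh: int, ow: int) -> np.ndarray:
    """[B, Hp, Wp, C] -> [B, OH, OW, m*m*C] patch matrix."""
    b, _, _, c = xp.shape
    v = np.lib.stride_tricks.sliding_window_view(xp, (m, m), axis=(1, 2))
    v = v[:, :: s, :: s][:, :oh, :ow]  # (B, OH, OW, C, m, m)
    return np.ascontiguousarray(v.transpose(0, 1, 2, 4, 5, 3)).reshape(b, oh, ow, m * m * c)


def _col2im(gcols: np.ndarray, xp_shape, m: int, s: int, oh: int, ow: int) -> np.ndarray:
    b, hp, wp, c = xp_shape
    g = gcols.reshape(b, oh, ow, m * m, c)
    out = np.zeros(xp_shape, dtype=gcols.dtype)
    for ki in range(m):
        for kj in range(m):
            out[:, ki : ki + s * oh : s, kj : kj + s * ow : s, :] += g[:, :, :, ki * m + kj, :]
    return out


def conv2d(x, w, bias=None, stride: int = 1, padding: str = "same"):
    """2-D convolution (cross-correlation), x: [B,H,W,Cin], w: [m,m,Cin,Cout]."""
    if padding not in ("same", "valid"):
        raise ValueError(f"unknown padding {padding!r}")
    xt = isinstance(x, Tensor) or isinstance(w, Tensor) or isinstance(bias, Tensor)
    x, w = _wrap(x), _wrap(w)
    if bias is not None:
        bias = _wrap(bias)
    xd, wd = x.data, w.data
    m = wd.shape[0]
    if wd.shape[2] != xd.shape[3]:
        raise ValueError(f"channel mismatch: input {xd.shape[3]}, kernel {wd.shape[2]}")
    b_, h, wdt, cin = xd.shape
    oh, ow = _out_size(h, m, stride, padding), _out_size(wdt, m, stride, padding)
    if oh < 1 or ow < 1:
        raise ValueError("spatial size smaller than kernel under 'valid' padding")
    if padding == "same":
        (pt, pb), (pl, pr) = _same_pad(h, m, stride), _same_pad(wdt, m, stride)
        xp = np.pad(xd, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    else:
        pt = pl = 0
        xp = xd
    cols = _im2col(xp, m, stride, oh, ow)
    wmat = wd.reshape(m * m * cin, -1)
    yd = cols @ wmat
    if bias is not None:
        yd = yd + bias.data
    if not xt:
        return yd
    parents = (x, w) if bias is None else (x, w, bias)
    out = Tensor(yd, parents=parents)

    def backward(g):
        g2 = g.reshape(-1, g.shape[-1])
        if w.requires_grad:
            w._accumulate((cols.reshape(-1, cols.shape[-1]).T @ g2).reshape(wd.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g2.sum(axis=0))
        if x.requires_grad:
            gcols = (g2 @ wmat.T).reshape(cols.shape)
            gxp = _col2im(gcols, xp.shape, m, stride, oh, ow)
            if padding == "same":
                gxp = gxp[:, pt : pt + h, pl : pl + wdt, :]
            x._accumulate(gxp)

    out._backward = backward
    return out


def maxpool2d(x, size: int = 3, stride: int = 2, padding: str = "same"):
    """Max-pooling over size×size windows; 'same' padding uses -inf fill."""
    xt = isinstance(x, Tensor)
    x = _wrap(x)
    xd = x.data
    b_, h, w_, c = xd.shape
    oh, ow = _out_size(h, size, stride, padding), _out_size(w_, size, stride, padding)
    if padding == "same":
        (pt, pb), (pl, pr) = _same_pad(h, size, stride), _same_pad(w_, size, stride)
        xp = np.pad(xd, ((0, 0), (pt, pb), (pl, pr), (0, 0)), constant_values=-np.inf)
    else:
        pt = pl = 0
        xp = xd
    stacked = np.empty((b_, oh, ow, c, size * size), dtype=xd.dtype)
    for ki in range(size):
        for kj in range(size):
            stacked[..., ki * size + kj] = xp[:, ki : ki + stride * oh : stride, kj : kj + stride * ow : stride, :]
    arg = stacked.argmax(axis=-1)
    yd = np.take_along_axis(stacked, arg[..., None], axis=-1)[..., 0]
    if not xt:
        return yd
    out = Tensor(yd, parents=(x,))

    def backward(g):
        if not x.requires_grad:
            return
        gxp = np.zeros(xp.shape, dtype=g.dtype)
        for ki in range(size):
            for kj in range(size):
                mask = arg == (ki * size + kj)
                gxp[:, ki : ki + stride * oh : stride, kj : kj + stride * ow : stride, :] += g * mask
        if padding == "same":
            gxp = gxp[:, pt : pt + h, pl : pl + w_, :]
        x._accumulate(gxp)

    out._backward = backward
    return out
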