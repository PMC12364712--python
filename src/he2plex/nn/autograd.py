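"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine exists to train the translator/discriminator pair and the MIL
heads on a single CPU.  It supports second-order gradients (backward passes
are themselves built out of differentiable primitives), which the R1
gradient penalty needs: the penalty is a function of ``dD/dy`` and its
gradient with respect to the discriminator weights must flow through that
inner derivative.

Only the primitives required by the package are implemented.  Convolution,
padding, up/down-sampling and patch gathering are all expressed through two
linear primitive pairs (gather/scatter-add along the last axis and basic
slicing/scatter), so their adjoints — and the adjoints of the adjoints —
come for free.
"""
from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

_GRAD_ENABLED = True
_DTYPE = np.float64


@contextlib.contextmanager
def no_grad():
    """Disable graph recording (inference / optimizer internals)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


@contextlib.contextmanager
def default_dtype(dtype):
    """Set the float dtype for tensors created inside the block.

    float64 is the default (oracle-grade precision); training loops use
    float32 for throughput.
    """
    global _DTYPE
    prev = _DTYPE
    _DTYPE = np.dtype(dtype)
    try:
        yield
    finally:
        _DTYPE = prev


class Tensor:
    __slots__ = ("data", "parents", "bwd", "requires_grad", "grad")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), bwd: Callable | None = None):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.parents = parents
        self.bwd = bwd
        self.requires_grad = bool(requires_grad)
        self.grad = None  # numpy array, filled by `backward`

    # -- basic introspection -------------------------------------------------
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

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def item(self) -> float:
        return float(self.data)

    # -- operators -----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return add(self, neg(astensor(other)))

    def __rsub__(self, other):
        return add(astensor(other), neg(self))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        return mul(self, pow_const(other, -1.0))

    def __rtruediv__(self, other):
        return mul(astensor(other), pow_const(self, -1.0))

    def __pow__(self, p):
        return pow_const(self, float(p))

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, key):
        return getitem(self, key)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes if axes else None)

    @property
    def T(self):
        return transpose(self, None)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, bwd) -> Tensor:
    """Create an op output; records the graph only when some parent needs it."""
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        return Tensor(data, requires_grad=True, parents=parents, bwd=bwd)
    return Tensor(data)


# ---------------------------------------------------------------------------
# broadcasting helper (sum incoming gradient down to a parent's shape)
# ---------------------------------------------------------------------------

def _sum_to(g: Tensor, shape: tuple) -> Tensor:
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(i for i, (gs, s) in enumerate(zip(g.shape, shape)) if s == 1 and gs != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != shape:
        g = reshape(g, shape)
    return g


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    return _make(a.data + b.data, (a, b),
                 lambda g: (_sum_to(g, a.shape), _sum_to(g, b.shape)))


def neg(a) -> Tensor:
    a = astensor(a)
    return _make(-a.data, (a,), lambda g: (neg(g),))


def mul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    return _make(a.data * b.data, (a, b),
                 lambda g: (_sum_to(mul(g, b), a.shape), _sum_to(mul(g, a), b.shape)))


def pow_const(a, p: float) -> Tensor:
    a = astensor(a)
    return _make(a.data ** p, (a,),
                 lambda g: (mul(g, mul_const(pow_const(a, p - 1.0), p)),))


def mul_const(a, c: float) -> Tensor:
    a = astensor(a)
    return _make(a.data * c, (a,), lambda g: (mul_const(g, c),))


def texp(a) -> Tensor:
    a = astensor(a)
    out_data = np.exp(a.data)
    out = _make(out_data, (a,), None)
    if out.requires_grad:
        out.bwd = lambda g: (mul(g, out),)
    return out


def tlog(a) -> Tensor:
    a = astensor(a)
    return _make(np.log(a.data), (a,), lambda g: (mul(g, pow_const(a, -1.0)),))


def tsqrt(a) -> Tensor:
    return pow_const(astensor(a), 0.5)


def tanh(a) -> Tensor:
    a = astensor(a)
    out_data = np.tanh(a.data)
    out = _make(out_data, (a,), None)
    if out.requires_grad:
        out.bwd = lambda g: (mul(g, add(1.0, neg(mul(out, out)))),)
    return out


def sigmoid(a) -> Tensor:
    a = astensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))
    out = _make(out_data, (a,), None)
    if out.requires_grad:
        out.bwd = lambda g: (mul(g, mul(out, add(1.0, neg(out)))),)
    return out


def relu(a) -> Tensor:
    a = astensor(a)
    mask = (a.data > 0).astype(_DTYPE)
    return _make(a.data * mask, (a,), lambda g: (mul(g, Tensor(mask)),))


def tabs(a) -> Tensor:
    a = astensor(a)
    sign = np.sign(a.data)
    return _make(np.abs(a.data), (a,), lambda g: (mul(g, Tensor(sign)),))


def clamp(a, lo: float, hi: float) -> Tensor:
    a = astensor(a)
    mask = ((a.data >= lo) & (a.data <= hi)).astype(_DTYPE)
    return _make(np.clip(a.data, lo, hi), (a,), lambda g: (mul(g, Tensor(mask)),))


def matmul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)

    def bwd(g):
        return (matmul(g, transpose(b, None)), matmul(transpose(a, None), g))

    return _make(a.data @ b.data, (a, b), bwd)


def transpose(a, axes=None) -> Tensor:
    a = astensor(a)
    if axes is None:
        axes = tuple(range(a.ndim))[::-1]
    inv = tuple(np.argsort(axes))
    return _make(np.transpose(a.data, axes), (a,), lambda g: (transpose(g, inv),))


def reshape(a, shape) -> Tensor:
    a = astensor(a)
    orig = a.shape
    return _make(a.data.reshape(shape), (a,), lambda g: (reshape(g, orig),))


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    orig = a.shape

    def bwd(g):
        if axis is None:
            kd = (1,) * len(orig)
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            axes = tuple(ax % len(orig) for ax in axes)
            kd = tuple(1 if i in axes else s for i, s in enumerate(orig))
        gk = g if keepdims else reshape(g, kd)
        return (expand(gk, orig),)

    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    if axis is None:
        n = a.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul_const(tsum(a, axis, keepdims), 1.0 / n)


def expand(a, shape) -> Tensor:
    a = astensor(a)
    orig = a.shape
    return _make(np.broadcast_to(a.data, shape).copy(), (a,),
                 lambda g: (_sum_to(g, orig),))


def concat(tensors: Sequence, axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def bwd(g):
        outs = []
        for i, t in enumerate(tensors):
            key = [slice(None)] * g.ndim
            key[axis] = slice(int(offs[i]), int(offs[i + 1]))
            outs.append(getitem(g, tuple(key)))
        return tuple(outs)

    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), bwd)


def getitem(a, key) -> Tensor:
    """Basic (slice/int) indexing; adjoint scatters into zeros."""
    a = astensor(a)
    shape = a.shape
    return _make(a.data[key].copy(), (a,), lambda g: (scatter_basic(g, shape, key),))


def scatter_basic(g, shape, key) -> Tensor:
    g = astensor(g)
    z = np.zeros(shape, dtype=_DTYPE)
    z[key] = g.data
    return _make(z, (g,), lambda gg: (getitem(gg, key),))


def gather_last(a, idx: np.ndarray) -> Tensor:
    """out[..., k] = a[..., idx[k]]; adjoint is scatter-add."""
    a = astensor(a)
    idx = np.asarray(idx, dtype=np.intp)
    m = a.shape[-1]
    return _make(a.data[..., idx], (a,),
                 lambda g: (scatter_add_last(g, idx, m),))


def scatter_add_last(g, idx: np.ndarray, m: int) -> Tensor:
    g = astensor(g)
    idx = np.asarray(idx, dtype=np.intp)
    batch = g.shape[:-1]
    g2 = g.data.reshape(-1, g.shape[-1])
    z = np.zeros((m, g2.shape[0]), dtype=_DTYPE)
    np.add.at(z, idx, g2.T)
    out = z.T.reshape(batch + (m,))
    return _make(out, (g,), lambda gg: (gather_last(gg, idx),))


# ---------------------------------------------------------------------------
# composite image ops
# ---------------------------------------------------------------------------

def pad2d(x, pad: int, mode: str = "zero") -> Tensor:
    """Pad the last two axes. mode in {'zero', 'reflect', 'edge'}."""
    x = astensor(x)
    if pad == 0:
        return x
    *lead, h, w = x.shape
    if mode == "zero":
        shape = tuple(lead) + (h + 2 * pad, w + 2 * pad)
        key = (Ellipsis, slice(pad, pad + h), slice(pad, pad + w))
        return scatter_basic(x, shape, key)
    np_mode = {"reflect": "reflect", "edge": "edge"}[mode]
    src = np.pad(np.arange(h * w).reshape(h, w), pad, mode=np_mode)
    flat = reshape(x, tuple(lead) + (h * w,))
    out = gather_last(flat, src.ravel())
    return reshape(out, tuple(lead) + (h + 2 * pad, w + 2 * pad))


def im2col(x, kh: int, kw: int, stride: int) -> Tensor:
    """Unfold (N, C, H, W) into (N*OH*OW, C*kh*kw) patch rows.

    Forward uses a sliding-window view (single copy); the adjoint is
    `col2im`, a vectorized slice-accumulate — together they give
    convolution (and its double backward) without generic scatter-adds.
    """
    x = astensor(x)
    n, c, h, w = x.shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1

    def fwd(data):
        win = np.lib.stride_tricks.sliding_window_view(data, (kh, kw), axis=(2, 3))
        win = win[:, :, ::stride, ::stride]              # (n, c, oh, ow, kh, kw)
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * kh * kw)

    return _make(fwd(x.data), (x,),
                 lambda g: (col2im(g, (n, c, h, w), kh, kw, stride),))


def col2im(cols, xshape: tuple, kh: int, kw: int, stride: int) -> Tensor:
    cols = astensor(cols)
    n, c, h, w = xshape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1

    def fwd(data):
        g6 = data.reshape(n, oh, ow, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        out = np.zeros((n, c, h, w), dtype=_DTYPE)
        for i in range(kh):
            for j in range(kw):
                out[:, :, i:i + stride * oh:stride,
                    j:j + stride * ow:stride] += g6[:, :, :, :, i, j]
        return out

    return _make(fwd(cols.data), (cols,),
                 lambda g: (im2col(g, kh, kw, stride),))


def conv2d(x, weight, bias=None, stride: int = 1, padding: int = 0,
           pad_mode: str = "zero") -> Tensor:
    """NCHW cross-correlation. weight: (F, C, kh, kw), bias: (F,)."""
    x = astensor(x)
    weight = astensor(weight)
    if padding:
        x = pad2d(x, padding, pad_mode)
    n, c, h, w = x.shape
    f, cw, kh, kw = weight.shape
    if cw != c:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {cw}")
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    patches = im2col(x, kh, kw, stride)                 # (n*oh*ow, c*kh*kw)
    wmat = reshape(weight, (f, c * kh * kw))
    out = matmul(patches, transpose(wmat, None))        # (n*oh*ow, f)
    out = reshape(out, (n, oh, ow, f))
    out = transpose(out, (0, 3, 1, 2))
    if bias is not None:
        out = add(out, reshape(astensor(bias), (1, f, 1, 1)))
    return out


def depthwise_blur(x, kernel1d: np.ndarray, pad_mode: str = "reflect") -> Tensor:
    """Separable symmetric blur applied independently to every channel."""
    x = astensor(x)
    n, c, h, w = x.shape
    k = len(kernel1d)
    pad = k // 2
    xr = reshape(x, (n * c, 1, h, w))
    kv = Tensor(np.asarray(kernel1d, dtype=_DTYPE).reshape(1, 1, k, 1))
    kh = Tensor(np.asarray(kernel1d, dtype=_DTYPE).reshape(1, 1, 1, k))
    y = pad2d(xr, pad, pad_mode)
    y = conv2d(y, kv)
    y = conv2d(y, kh)
    # the two 1-D convs each consumed `pad` on one axis only; crop the excess
    y = getitem(y, (Ellipsis, slice(0, h), slice(0, w))) if y.shape[-2:] != (h, w) else y
    return reshape(y, (n, c, h, w))


def decimate2(x) -> Tensor:
    return getitem(astensor(x), (Ellipsis, slice(None, None, 2), slice(None, None, 2)))


def upsample_nearest2(x) -> Tensor:
    x = astensor(x)
    *lead, h, w = x.shape
    src = np.repeat(np.repeat(np.arange(h * w).reshape(h, w), 2, 0), 2, 1)
    flat = reshape(x, tuple(lead) + (h * w,))
    return reshape(gather_last(flat, src.ravel()), tuple(lead) + (2 * h, 2 * w))


def avg_pool2d(x, k: int) -> Tensor:
    x = astensor(x)
    n, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError("avg_pool2d: spatial size not divisible by kernel")
    y = reshape(x, (n, c, h // k, k, w // k, k))
    return tmean(y, axis=(3, 5))


def softmax(x, axis: int = -1) -> Tensor:
    x = astensor(x)
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # detached; softmax is shift-invariant
    e = texp(add(x, neg(shift)))
    return mul(e, pow_const(tsum(e, axis=axis, keepdims=True), -1.0))


# ---------------------------------------------------------------------------
# backprop driver
# ---------------------------------------------------------------------------

def grad(out: Tensor, wrt: Sequence[Tensor], create_graph: bool = False,
         accumulate: bool = False) -> list[Tensor]:
    """Gradients of scalar `out` w.r.t. each tensor in `wrt`.

    With ``create_graph=True`` the returned gradients carry their own graph,
    so expressions built from them (for example the R1 penalty) can be
    differentiated again.
    """
    if out.size != 1:
        raise ValueError("grad expects a scalar output")
    topo: list[Tensor] = []
    seen: set[int] = set()

    def visit(t: Tensor):
        stack = [(t, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))

    visit(out)
    grads: dict[int, Tensor] = {id(out): Tensor(np.ones(out.shape))}
    wrt_ids = {id(w) for w in wrt}
    result: dict[int, Tensor] = {}
    for node in reversed(topo):
        g = grads.pop(id(node), None)
        if g is None:
            continue
        if id(node) in wrt_ids:
            result[id(node)] = add(result[id(node)], g) if id(node) in result else g
        if node.bwd is None:
            continue
        parent_grads = node.bwd(g)
        for p, pg in zip(node.parents, parent_grads):
            if pg is None or not p.requires_grad:
                continue
            if not create_graph:
                pg = pg.detach()
            if id(p) in grads:
                grads[id(p)] = add(grads[id(p)], pg)
            else:
                grads[id(p)] = pg
    out_list = []
    for w in wrt:
        g = result.get(id(w))
        if g is None:
            g = Tensor(np.zeros(w.shape))
        out_list.append(g)
        if accumulate:
            w.grad = g.data if w.grad is None else w.grad + g.data
    return out_list
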