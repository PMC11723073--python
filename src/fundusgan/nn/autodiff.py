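"""Reverse-mode automatic differentiation on numpy arrays.

A small define-by-run tape supporting the handful of operations the
generator, critic and grader networks need.  Vector-Jacobian products are
themselves expressed with these same differentiable operations, so
``grad`` can be applied to the output of ``grad``: the second-order
derivatives required by the WGAN-GP gradient penalty (a loss on the norm
of an input gradient, differentiated again with respect to the critic's
parameters) come out of the same machinery.

Design notes
------------
* ``Tensor`` wraps an ``ndarray``; leaves created with
  ``requires_grad=True`` (parameters, or inputs whose saliency we want)
  participate in the tape, everything else is treated as a constant.
* Convolution is implemented as a trio of primitives — ``conv2d``,
  its input-adjoint ``conv2d_transpose`` and its weight-adjoint
  ``conv2d_weight_grad`` — whose VJPs are written in terms of each
  other, which closes the set under differentiation.
* Arithmetic is float64 by default, which keeps finite-difference and
  closed-form checks tight; float32 arrays pass through unpromoted (the
  adversarial training loop uses them as a CPU fast path), and scalar
  constants inside ops adopt the operand's dtype so a float32 graph
  stays float32 end to end.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float64


class Tensor:
    """A numpy array plus the tape bookkeeping for reverse-mode AD."""

    __slots__ = ("data", "requires_grad", "_parents", "_vjps")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        # float32 is honoured (training fast path); everything else is
        # promoted to the float64 default that all tolerance-sensitive
        # code relies on
        if arr.dtype != np.float32 and arr.dtype != DTYPE:
            arr = arr.astype(DTYPE)
        self.data = arr
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._vjps: tuple = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data.item())

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- operator sugar -------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return add(self, neg(as_tensor(other)))

    def __rsub__(self, other):
        return add(as_tensor(other), neg(self))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(as_tensor(other), power(self, -1.0))

    def __pow__(self, exponent):
        return power(self, exponent)

    def __matmul__(self, other):
        return matmul(self, other)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, vjps) -> Tensor:
    """Create an op-output tensor, recording the tape only where needed."""
    out = Tensor(data)
    tracked = [(p, v) for p, v in zip(parents, vjps) if p.requires_grad]
    if tracked:
        out.requires_grad = True
        out._parents = tuple(p for p, _ in tracked)
        out._vjps = tuple(v for _, v in tracked)
    return out


# ---------------------------------------------------------------------------
# broadcasting support
# ---------------------------------------------------------------------------

def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Sum ``g`` down to ``shape`` (adjoint of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    return reshape(g, shape)


# ---------------------------------------------------------------------------
# elementwise and reduction primitives
# ---------------------------------------------------------------------------

def _pair(a, b) -> tuple[Tensor, Tensor]:
    """Coerce operands, matching bare python/numpy scalars to the other
    operand's dtype so float32 graphs are not upcast by constants."""
    if isinstance(a, Tensor) and not isinstance(b, Tensor) and np.isscalar(b):
        b = Tensor(np.asarray(b, dtype=a.data.dtype))
    elif isinstance(b, Tensor) and not isinstance(a, Tensor) and np.isscalar(a):
        a = Tensor(np.asarray(a, dtype=b.data.dtype))
    return as_tensor(a), as_tensor(b)


def add(a, b) -> Tensor:
    a, b = _pair(a, b)
    return _make(
        a.data + b.data,
        (a, b),
        (lambda g: _unbroadcast(g, a.shape), lambda g: _unbroadcast(g, b.shape)),
    )


def neg(a) -> Tensor:
    a = as_tensor(a)
    return _make(-a.data, (a,), (lambda g: neg(g),))


def mul(a, b) -> Tensor:
    a, b = _pair(a, b)
    return _make(
        a.data * b.data,
        (a, b),
        (
            lambda g: _unbroadcast(mul(g, b), a.shape),
            lambda g: _unbroadcast(mul(g, a), b.shape),
        ),
    )


def power(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    e = float(exponent)
    return _make(
        a.data ** e,
        (a,),
        (lambda g: mul(g, mul(e, power(a, e - 1.0))),),
    )


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out = Tensor(np.exp(a.data))
    if a.requires_grad:
        out.requires_grad = True
        out._parents = (a,)
        out._vjps = (lambda g: mul(g, out),)
    return out


def log(a) -> Tensor:
    a = as_tensor(a)
    return _make(np.log(a.data), (a,), (lambda g: mul(g, power(a, -1.0)),))


def absolute(a) -> Tensor:
    a = as_tensor(a)
    sign = np.sign(a.data)
    return _make(np.abs(a.data), (a,), (lambda g: mul(g, Tensor(sign)),))


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = as_tensor(a)
    dt = a.data.dtype
    scale = np.where(a.data > 0, np.asarray(1.0, dt), np.asarray(slope, dt))
    return _make(a.data * scale, (a,), (lambda g: mul(g, Tensor(scale)),))


def relu(a) -> Tensor:
    return leaky_relu(a, 0.0)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(out_data)
    if a.requires_grad:
        out.requires_grad = True
        out._parents = (a,)
        out._vjps = (lambda g: mul(g, mul(out, add(1.0, neg(out)))),)
    return out


def tanh(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.tanh(a.data)
    out = Tensor(out_data)
    if a.requires_grad:
        out.requires_grad = True
        out._parents = (a,)
        out._vjps = (lambda g: mul(g, add(1.0, neg(mul(out, out)))),)
    return out


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            return broadcast_to(reshape(g, (1,) * a.ndim), a.shape)
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        if not keepdims:
            kshape = list(a.shape)
            for ax in axes:
                kshape[ax % a.ndim] = 1
            g = reshape(g, tuple(kshape))
        return broadcast_to(g, a.shape)

    return _make(data, (a,), (vjp,))


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        count = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        count = int(np.prod([a.shape[ax % a.ndim] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / count)


def broadcast_to(a, shape) -> Tensor:
    a = as_tensor(a)
    shape = tuple(shape)
    return _make(
        np.broadcast_to(a.data, shape),
        (a,),
        (lambda g: _unbroadcast(g, a.shape),),
    )


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    shape = tuple(shape)
    orig = a.shape
    return _make(a.data.reshape(shape), (a,), (lambda g: reshape(g, orig),))


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    return _make(a.data.transpose(axes), (a,), (lambda g: transpose(g, inv),))


def matmul(a, b) -> Tensor:
    """2-D matrix product."""
    a, b = as_tensor(a), as_tensor(b)

    def vjp_a(g):
        return matmul(g, transpose(b, (1, 0)))

    def vjp_b(g):
        return matmul(transpose(a, (1, 0)), g)

    return _make(a.data @ b.data, (a, b), (vjp_a, vjp_b))


def concat(tensors, axis: int) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        return lambda g: narrow(g, axis, int(offsets[i]), sizes[i])

    return _make(
        np.concatenate([t.data for t in tensors], axis=axis),
        tuple(tensors),
        tuple(make_vjp(i) for i in range(len(tensors))),
    )


def narrow(a, axis: int, start: int, length: int) -> Tensor:
    a = as_tensor(a)
    idx = [slice(None)] * a.ndim
    idx[axis] = slice(start, start + length)
    full = a.shape

    def vjp(g):
        return pad_zero(g, axis, start, full[axis] - start - length)

    return _make(a.data[tuple(idx)], (a,), (vjp,))


def pad_zero(a, axis: int, before: int, after: int) -> Tensor:
    a = as_tensor(a)
    widths = [(0, 0)] * a.ndim
    widths[axis] = (before, after)
    length = a.shape[axis]
    return _make(
        np.pad(a.data, widths),
        (a,),
        (lambda g: narrow(g, axis, before, length),),
    )


# ---------------------------------------------------------------------------
# convolution primitives (NCHW layout)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(N,C,H,W) -> (N, C*kh*kw, OH*OW) patch matrix."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hp, wp = x.shape[2], x.shape[3]
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    s = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kh, kw, oh, ow),
        strides=(s[0], s[1], s[2], s[3], s[2] * stride, s[3] * stride),
        writeable=False,
    )
    return view.reshape(n, c * kh * kw, oh * ow), oh, ow


def _col2im(cols: np.ndarray, x_shape, kh, kw, stride, pad):
    """Adjoint of _im2col: scatter-add patch matrix back to image."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    cols = cols.reshape(n, c, kh, kw, oh, ow)
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += cols[
                :, :, i, j
            ]
    if pad:
        out = out[:, :, pad : pad + h, pad : pad + w]
    return out


def _conv2d_fwd(x, w, stride, pad):
    n = x.shape[0]
    o, c, kh, kw = w.shape
    cols, oh, ow = _im2col(x, kh, kw, stride, pad)
    out = w.reshape(o, c * kh * kw) @ cols  # (o, ckk) @ (n, ckk, L) -> (n, o, L)
    return out.reshape(n, o, oh, ow)


def _conv2d_transpose_fwd(g, w, stride, pad, x_shape):
    n = g.shape[0]
    o, c, kh, kw = w.shape
    cols = w.reshape(o, c * kh * kw).T @ g.reshape(n, o, -1)  # (n, ckk, L)
    return _col2im(cols, x_shape, kh, kw, stride, pad)


def _conv2d_wgrad_fwd(x, g, stride, pad, w_shape):
    o, c, kh, kw = w_shape
    cols, oh, ow = _im2col(x, kh, kw, stride, pad)
    gm = g.reshape(g.shape[0], o, -1)  # (n, o, L)
    wg = np.einsum("nol,nkl->ok", gm, cols)
    return wg.reshape(o, c, kh, kw)


def conv2d(x, w, stride: int = 1, pad: int = 0) -> Tensor:
    x, w = as_tensor(x), as_tensor(w)
    x_shape, w_shape = x.shape, w.shape
    return _make(
        _conv2d_fwd(x.data, w.data, stride, pad),
        (x, w),
        (
            lambda g: conv2d_transpose(g, w, stride, pad, x_shape),
            lambda g: conv2d_weight_grad(x, g, stride, pad, w_shape),
        ),
    )


def conv2d_transpose(g, w, stride: int, pad: int, x_shape) -> Tensor:
    g, w = as_tensor(g), as_tensor(w)
    w_shape = w.shape
    return _make(
        _conv2d_transpose_fwd(g.data, w.data, stride, pad, x_shape),
        (g, w),
        (
            lambda c: conv2d(c, w, stride, pad),
            lambda c: conv2d_weight_grad(c, g, stride, pad, w_shape),
        ),
    )


def conv2d_weight_grad(x, g, stride: int, pad: int, w_shape) -> Tensor:
    x, g = as_tensor(x), as_tensor(g)
    x_shape = x.shape
    return _make(
        _conv2d_wgrad_fwd(x.data, g.data, stride, pad, w_shape),
        (x, g),
        (
            lambda c: conv2d_transpose(g, c, stride, pad, x_shape),
            lambda c: conv2d(x, c, stride, pad),
        ),
    )


# ---------------------------------------------------------------------------
# separable linear resampling (fixed weight matrices, e.g. resize kernels)
# ---------------------------------------------------------------------------

def lin2d(x, row_mat: np.ndarray, col_mat: np.ndarray) -> Tensor:
    """Apply ``row_mat @ img @ col_mat.T`` over the trailing two axes.

    ``row_mat``/``col_mat`` are constants (resize weight matrices), so the
    map is linear in ``x`` and its adjoint is ``lin2d`` with transposed
    matrices — the primitive closes under differentiation.
    """
    x = as_tensor(x)
    rm = np.asarray(row_mat, dtype=x.data.dtype)
    cm = np.asarray(col_mat, dtype=x.data.dtype)
    data = np.einsum("oh,...hw,pw->...op", rm, x.data, cm, optimize=True)
    return _make(data, (x,), (lambda g: lin2d(g, rm.T, cm.T),))


# ---------------------------------------------------------------------------
# the gradient engine
# ---------------------------------------------------------------------------

def grad(output: Tensor, inputs, cotangent: Tensor | None = None) -> list[Tensor]:
    """Cotangents of ``output`` with respect to each tensor in ``inputs``.

    The returned tensors are themselves on the tape, so expressions built
    from them (e.g. a gradient-norm penalty) can be differentiated again.
    Inputs unreachable from ``output`` get a zero cotangent.
    """
    single = isinstance(inputs, Tensor)
    inputs = [inputs] if single else list(inputs)
    if cotangent is None:
        cotangent = Tensor(np.ones_like(output.data))

    order: list[Tensor] = []
    seen: set[int] = set()
    stack = [(output, False)]
    while stack:
        node, expanded = stack.pop()
        if expanded:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in seen:
                stack.append((p, False))

    # prune: only propagate through nodes from which a requested input is
    # reachable — skipping e.g. weight-gradient convolutions of frozen
    # networks when only activations are differentiated
    input_ids = {id(t) for t in inputs}
    needed: set[int] = set()
    for node in order:  # forward-topological: parents precede children
        if id(node) in input_ids or any(id(p) in needed for p in node._parents):
            needed.add(id(node))

    cot: dict[int, Tensor] = {id(output): cotangent}
    for node in reversed(order):
        if id(node) not in needed:
            continue
        g = cot.get(id(node))
        if g is None:
            continue
        for parent, vjp in zip(node._parents, node._vjps):
            if id(parent) not in needed:
                continue
            contrib = vjp(g)
            prev = cot.get(id(parent))
            cot[id(parent)] = contrib if prev is None else add(prev, contrib)

    results = []
    for t in inputs:
        g = cot.get(id(t))
        results.append(g if g is not None else Tensor(np.zeros_like(t.data)))
    return results[0] if single else results
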