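"""Minimal reverse-mode automatic differentiation on numpy arrays.

The adversarial training in :mod:`ambientsom.ambient_gan` needs gradients of
scalar losses with respect to network parameters, including gradients *of
gradients* (the gradient-penalty and R1 regularizers differentiate the
discriminator's input-gradient norm with respect to the discriminator
parameters).  Every operation therefore expresses its vector-Jacobian product
in terms of other :class:`Tensor` operations, so calling :func:`grad` with
``create_graph=True`` yields gradients that are themselves differentiable.

Complex tensors are supported for the Fourier measurement channel.  For a
complex-linear map ``y = A x`` the backward rule uses the Wirtinger
convention ``g_x = A^H g_y`` with ``g = dL/dRe + i dL/dIm``; for the
(symmetric) DFT matrix this makes the adjoint of ``fft2`` a scaled ``ifft2``
and vice versa.

Only what the package needs is implemented: broadcasting elementwise
arithmetic, 2-D matmul, reductions, reshaping, rolls, leaky ReLU, sqrt / exp
/ log / softplus, and 2-D FFTs acting on the trailing two axes.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "grad",
    "no_grad",
    "is_grad_enabled",
    "concatenate",
    "stack",
]

_GRAD_ENABLED = True


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


@contextlib.contextmanager
def no_grad():
    """Disable graph recording (inference / first-order backward passes)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


@contextlib.contextmanager
def _set_grad(mode: bool):
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = mode
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    __slots__ = ("data", "requires_grad", "_vjps")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self._vjps: list[tuple["Tensor", Callable[["Tensor"], "Tensor"]]] = []

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __truediv__(self, other):
        other = as_tensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(as_tensor(other), power(self, -1.0))

    def __pow__(self, exponent):
        return power(self, exponent)

    def __matmul__(self, other):
        return matmul(self, other)

    @property
    def T(self):
        return transpose(self)

    def sum(self, axis=None, keepdims: bool = False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims: bool = False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parent_vjps: Iterable[tuple[Tensor, Callable]]) -> Tensor:
    """Create an op output, recording only live (grad-requiring) edges."""
    if not _GRAD_ENABLED:
        return Tensor(data)
    edges = [(p, f) for p, f in parent_vjps if p.requires_grad]
    out = Tensor(data, requires_grad=bool(edges))
    out._vjps = edges
    return out


# -- broadcasting helpers ---------------------------------------------------

def _unbroadcast(g: Tensor, shape: tuple[int, ...]) -> Tensor:
    """Sum gradient ``g`` back down to ``shape`` after numpy broadcasting."""
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(
        i for i, (gs, s) in enumerate(zip(g.shape, shape)) if s == 1 and gs != 1
    )
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != shape:
        g = reshape(g, shape)
    return g


def broadcast_to(x, shape) -> Tensor:
    x = as_tensor(x)
    data = np.broadcast_to(x.data, shape)
    return _node(data, [(x, lambda g: _unbroadcast(g, x.shape))])


# -- elementwise ------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _node(
        a.data + b.data,
        [(a, lambda g: _unbroadcast(g, a.shape)), (b, lambda g: _unbroadcast(g, b.shape))],
    )


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _node(
        a.data * b.data,
        [
            (a, lambda g: _unbroadcast(mul(g, b), a.shape)),
            (b, lambda g: _unbroadcast(mul(g, a), b.shape)),
        ],
    )


def power(x, exponent: float) -> Tensor:
    """Elementwise power with a constant (real) exponent."""
    x = as_tensor(x)
    e = float(exponent)
    data = x.data**e
    return _node(data, [(x, lambda g: mul(g, mul(power(x, e - 1.0), e)))])


def sqrt(x) -> Tensor:
    return power(x, 0.5)


def texp(x) -> Tensor:
    x = as_tensor(x)
    out = _node(np.exp(x.data), [(x, lambda g: mul(g, out))])
    return out


def tlog(x) -> Tensor:
    x = as_tensor(x)
    return _node(np.log(x.data), [(x, lambda g: mul(g, power(x, -1.0)))])


def softplus(x) -> Tensor:
    """log(1 + exp(x)), numerically stable.

    The backward coefficient sigmoid(x) is treated as a constant, so second
    derivatives through softplus are not tracked (the regularizers that need
    double backward differentiate raw discriminator scores, not the loss).
    """
    x = as_tensor(x)
    data = np.logaddexp(0.0, x.data)
    sig = Tensor(1.0 / (1.0 + np.exp(-x.data)))
    return _node(data, [(x, lambda g: mul(g, sig))])


def leaky_relu(x, slope: float = 0.2) -> Tensor:
    x = as_tensor(x)
    mask = Tensor(np.where(x.data > 0, 1.0, slope))
    return _node(x.data * mask.data, [(x, lambda g: mul(g, mask))])


def relu(x) -> Tensor:
    return leaky_relu(x, 0.0)


# -- shape ops --------------------------------------------------------------

def reshape(x, shape) -> Tensor:
    x = as_tensor(x)
    shape = tuple(shape)
    return _node(x.data.reshape(shape), [(x, lambda g: reshape(g, x.shape))])


def transpose(x, axes: Sequence[int] | None = None) -> Tensor:
    x = as_tensor(x)
    data = np.transpose(x.data, axes)
    if axes is None:
        inv = None
    else:
        inv = tuple(np.argsort(axes))
    return _node(data, [(x, lambda g: transpose(g, inv))])


def roll(x, shift: int, axis: int) -> Tensor:
    x = as_tensor(x)
    return _node(
        np.roll(x.data, shift, axis=axis), [(x, lambda g: roll(g, -shift, axis))]
    )


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        def vjp(g):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
            return getitem(g, tuple(sl))

        return vjp

    return _node(data, [(t, make_vjp(i)) for i, t in enumerate(tensors)])


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    return concatenate([reshape(t, t.shape[:axis] + (1,) + t.shape[axis:]) for t in
                        [as_tensor(t) for t in tensors]], axis=axis)


def getitem(x, index) -> Tensor:
    x = as_tensor(x)
    data = x.data[index]
    return _node(data, [(x, lambda g: _scatter(g, x.shape, index))])


def _scatter(g: Tensor, shape, index) -> Tensor:
    data = np.zeros(shape, dtype=g.dtype)
    np.add.at(data, index, g.data)
    return _node(data, [(g, lambda h: getitem(h, index))])


# -- reductions -------------------------------------------------------------

def tsum(x, axis=None, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    data = x.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            return broadcast_to(reshape(g, (1,) * x.ndim), x.shape)
        axes = axis if isinstance(axis, tuple) else (axis,)
        axes = tuple(a % x.ndim for a in axes)
        if keepdims:
            gk = g
        else:
            kshape = tuple(1 if i in axes else s for i, s in enumerate(x.shape))
            gk = reshape(g, kshape)
        return broadcast_to(gk, x.shape)

    return _node(data, [(x, vjp)])


def tmean(x, axis=None, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    if axis is None:
        n = x.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([x.shape[a % x.ndim] for a in axes]))
    return mul(tsum(x, axis=axis, keepdims=keepdims), 1.0 / n)


# -- linear algebra ---------------------------------------------------------

def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("matmul supports 2-D operands only")
    return _node(
        a.data @ b.data,
        [
            (a, lambda g: matmul(g, transpose(b))),
            (b, lambda g: matmul(transpose(a), g)),
        ],
    )


# -- complex / Fourier ------------------------------------------------------

def fft2(x) -> Tensor:
    """2-D DFT over the trailing two axes (non-unitary forward)."""
    x = as_tensor(x)
    n = x.shape[-1] * x.shape[-2]
    return _node(np.fft.fft2(x.data), [(x, lambda g: mul(ifft2(g), float(n)))])


def ifft2(x) -> Tensor:
    """2-D inverse DFT over the trailing two axes (carries 1/(H*W))."""
    x = as_tensor(x)
    n = x.shape[-1] * x.shape[-2]
    return _node(np.fft.ifft2(x.data), [(x, lambda g: mul(fft2(g), 1.0 / float(n)))])


def real(z) -> Tensor:
    z = as_tensor(z)
    return _node(np.real(z.data), [(z, lambda g: g)])


def imag(z) -> Tensor:
    z = as_tensor(z)
    return _node(np.imag(z.data), [(z, lambda g: mul(g, 1j))])


def cabs(z, eps: float = 1e-12) -> Tensor:
    """Complex modulus; backward coefficient z/|z| held constant."""
    z = as_tensor(z)
    mag = np.abs(z.data)
    coeff = Tensor(z.data / (mag + eps))
    return _node(mag, [(z, lambda g: mul(g, coeff))])


# -- autodiff driver --------------------------------------------------------

def _topo(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack_: list[tuple[Tensor, bool]] = [(root, False)]
    while stack_:
        node, processed = stack_.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack_.append((node, True))
        for parent, _ in node._vjps:
            if id(parent) not in seen:
                stack_.append((parent, False))
    return order


def grad(
    output: Tensor,
    inputs: Sequence[Tensor],
    grad_output: Tensor | None = None,
    create_graph: bool = False,
) -> list[Tensor]:
    """Gradients of ``output`` w.r.t. ``inputs``.

    With ``create_graph=True`` the returned tensors carry their own graph, so
    they can be differentiated again (used by gradient-penalty terms).
    """
    if grad_output is None:
        seed = Tensor(np.ones_like(output.data, dtype=np.result_type(output.dtype, float)))
    else:
        seed = as_tensor(grad_output)
    table: dict[int, Tensor] = {id(output): seed}
    order = _topo(output)
    with _set_grad(create_graph):
        for node in reversed(order):
            g = table.pop(id(node), None)
            if g is None:
                continue
            # a real-valued node has a real gradient; complex contributions
            # (Wirtinger grads arriving from downstream complex ops) project
            # onto their real part here
            if not np.iscomplexobj(node.data) and np.iscomplexobj(g.data):
                g = real(g)
            for parent, vjp in node._vjps:
                contrib = vjp(g)
                prev = table.get(id(parent))
                table[id(parent)] = contrib if prev is None else add(prev, contrib)
            # keep gradients requested by the caller
            for t in inputs:
                if t is node:
                    table[id(node)] = g
    out = []
    for t in inputs:
        g = table.get(id(t))
        if g is None:
            g = Tensor(np.zeros_like(t.data))
        out.append(g)
    return out
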