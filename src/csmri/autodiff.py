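"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides a :class:`Tensor` wrapping a float64 ``numpy.ndarray`` together with
the small set of differentiable operations the reconstruction networks need:
elementwise arithmetic with broadcasting, activations, reductions, 2-D
(dilated, strided) convolution, pooling, bilinear upsampling and channel
concatenation.  Gradients are accumulated by a topological backward sweep, in
the style familiar from tape-based frameworks.

Everything is computed in float64 so that gradient checks against central
finite differences are meaningful to ~1e-7.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "max_pool2d",
    "global_avg_pool",
    "global_max_pool",
    "upsample_bilinear",
    "interp_matrix",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], Iterable[np.ndarray | None]] | None = None

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    # -- graph machinery ---------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this (typically scalar) tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: Tensor) -> None:
            # iterative DFS to avoid recursion limits on deep graphs
            stack: list[tuple[Tensor, bool]] = [(node, False)]
            while stack:
                cur, processed = stack.pop()
                if processed:
                    topo.append(cur)
                    continue
                if id(cur) in seen:
                    continue
                seen.add(id(cur))
                stack.append((cur, True))
                for p in cur._parents:
                    if id(p) not in seen:
                        stack.append((p, False))

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            parent_grads = node._backward(g)
            for parent, pg in zip(node._parents, parent_grads):
                if pg is None or not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                elif parent._backward is None:
                    # leaf: accumulate directly
                    parent.grad = pg if parent.grad is None else parent.grad + pg
                else:
                    grads[id(parent)] = pg

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = _node(self.data + other.data, (self, other))
        if out._parents:
            out._backward = lambda g: (
                _unbroadcast(g, self.shape),
                _unbroadcast(g, other.shape),
            )
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))
        if out._parents:
            out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = _node(self.data * other.data, (self, other))
        if out._parents:
            out._backward = lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = _node(self.data / other.data, (self, other))
        if out._parents:
            out._backward = lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = _node(self.data**exponent, (self,))
        if out._parents:
            out._backward = lambda g: (g * exponent * self.data ** (exponent - 1),)
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = _node(self.data @ other.data, (self, other))
        if out._parents:
            out._backward = lambda g: (g @ other.data.T, self.data.T @ g)
        return out

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _node(self.data.reshape(shape), (self,))
        if out._parents:
            out._backward = lambda g: (g.reshape(self.shape),)
        return out

    # -- elementwise nonlinearities ----------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = _node(np.where(mask, self.data, 0.0), (self,))
        if out._parents:
            out._backward = lambda g: (g * mask,)
        return out

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        mask = self.data > 0
        out = _node(np.where(mask, self.data, slope * self.data), (self,))
        if out._parents:
            out._backward = lambda g: (g * np.where(mask, 1.0, slope),)
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = _node(s, (self,))
        if out._parents:
            out._backward = lambda g: (g * s * (1.0 - s),)
        return out

    def log(self) -> "Tensor":
        out = _node(np.log(self.data), (self,))
        if out._parents:
            out._backward = lambda g: (g / self.data,)
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = _node(e, (self,))
        if out._parents:
            out._backward = lambda g: (g * e,)
        return out

    def sqrt(self) -> "Tensor":
        return self**0.5

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient passes only where unclamped."""
        mask = (self.data > lo) & (self.data < hi)
        out = _node(np.clip(self.data, lo, hi), (self,))
        if out._parents:
            out._backward = lambda g: (g * mask,)
        return out

    def abs(self) -> "Tensor":
        s = np.sign(self.data)
        out = _node(np.abs(self.data), (self,))
        if out._parents:
            out._backward = lambda g: (g * s,)
        return out

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out._parents:
            def back(g: np.ndarray):
                if axis is None:
                    return (np.broadcast_to(g, self.shape).copy(),)
                gg = g
                if not keepdims:
                    gg = np.expand_dims(gg, axis)
                return (np.broadcast_to(gg, self.shape).copy(),)
            out._backward = back
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: Sequence[Tensor]) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
    return out


# ---------------------------------------------------------------------------
# structural ops
# ---------------------------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    if out._parents:
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        out._backward = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    dilation: int = 1,
    padding: int = 0,
) -> Tensor:
    """2-D cross-correlation over NCHW batches.

    The kernel-tap loop (at most k*k iterations) keeps memory flat while every
    inner contraction is a BLAS matmul via einsum.
    """
    xd, wd = x.data, weight.data
    n, c, h, w = xd.shape
    co, ci, kh, kw = wd.shape
    if ci != c:
        raise ValueError(f"channel mismatch: input has {c}, kernel expects {ci}")
    s, d, p = stride, dilation, padding
    xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p))) if p else xd
    hp, wp = xp.shape[2:]
    ho = (hp - ((kh - 1) * d + 1)) // s + 1
    wo = (wp - ((kw - 1) * d + 1)) // s + 1
    if ho <= 0 or wo <= 0:
        raise ValueError("kernel larger than (padded) input")

    def tap(arr, ph, pw):
        return arr[:, :, ph * d : ph * d + s * (ho - 1) + 1 : s,
                   pw * d : pw * d + s * (wo - 1) + 1 : s]

    y = np.zeros((n, co, ho, wo))
    for ph in range(kh):
        for pw in range(kw):
            y += np.einsum("nchw,oc->nohw", tap(xp, ph, pw), wd[:, :, ph, pw],
                           optimize=True)
    if bias is not None:
        y += bias.data.reshape(1, -1, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)
    out = _node(y, parents)
    if out._parents:
        def back(g: np.ndarray):
            gx = np.zeros_like(xp)
            gw = np.zeros_like(wd)
            for ph in range(kh):
                for pw in range(kw):
                    gw[:, :, ph, pw] = np.einsum(
                        "nohw,nchw->oc", g, tap(xp, ph, pw), optimize=True)
                    tap(gx, ph, pw)[...] += np.einsum(
                        "nohw,oc->nchw", g, wd[:, :, ph, pw], optimize=True)
            if p:
                gx = gx[:, :, p:-p, p:-p]
            gb = g.sum(axis=(0, 2, 3)) if bias is not None else None
            return (gx, gw, gb) if bias is not None else (gx, gw)
        out._backward = back
    return out


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def max_pool2d(x: Tensor, kernel: int = 2) -> Tensor:
    xd = x.data
    n, c, h, w = xd.shape
    k = kernel
    if h % k or w % k:
        raise ValueError(f"spatial size {h}x{w} not divisible by pool size {k}")
    ho, wo = h // k, w // k
    windows = xd.reshape(n, c, ho, k, wo, k).transpose(0, 1, 2, 4, 3, 5)
    flat = windows.reshape(n, c, ho, wo, k * k)
    idx = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    out = _node(y, (x,))
    if out._parents:
        def back(g: np.ndarray):
            gflat = np.zeros_like(flat)
            np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
            gx = gflat.reshape(n, c, ho, wo, k, k).transpose(0, 1, 2, 4, 3, 5)
            return (gx.reshape(n, c, h, w),)
        out._backward = back
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """NCHW -> NC mean over the spatial extent."""
    return x.mean(axis=(2, 3))


def global_max_pool(x: Tensor) -> Tensor:
    """NCHW -> NC max over the spatial extent."""
    xd = x.data
    n, c, h, w = xd.shape
    flat = xd.reshape(n, c, h * w)
    idx = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    out = _node(y, (x,))
    if out._parents:
        def back(g: np.ndarray):
            gflat = np.zeros_like(flat)
            np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
            return (gflat.reshape(n, c, h, w),)
        out._backward = back
    return out


# ---------------------------------------------------------------------------
# bilinear upsampling
# ---------------------------------------------------------------------------

def interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Corner-aligned 1-D linear interpolation matrix (n_out x n_in)."""
    if n_in == 1:
        return np.ones((n_out, 1))
    pos = np.linspace(0.0, n_in - 1.0, n_out)
    i0 = np.minimum(np.floor(pos).astype(int), n_in - 2)
    frac = pos - i0
    m = np.zeros((n_out, n_in))
    rows = np.arange(n_out)
    m[rows, i0] = 1.0 - frac
    m[rows, i0 + 1] += frac
    return m


def upsample_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Separable corner-aligned bilinear resampling of NCHW tensors.

    Exact on constants everywhere and on linear ramps at interior positions;
    the adjoint (transposed interpolation) serves as the backward pass.
    """
    n, c, h, w = x.shape
    mh = interp_matrix(h, out_h)
    mw = interp_matrix(w, out_w)
    y = np.matmul(np.matmul(mh, x.data), mw.T)
    out = _node(y, (x,))
    if out._parents:
        out._backward = lambda g: (np.matmul(np.matmul(mh.T, g), mw),)
    return out
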