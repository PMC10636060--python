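"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine powering the geometry-prediction network and its
training loop.  Only the operations the network needs are implemented:
broadcast arithmetic, (batched) matmul, reductions, softmax/layernorm, a 3x3
same-padding convolution for the multi-scale pair updates, and indexing.

Everything is float64.  Gradients accumulate into ``Tensor.grad`` after
``backward()`` on a scalar.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "stack", "conv3x3"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a numpy array."""

    __slots__ = ("v", "grad", "_parents", "_bwd", "requires_grad")

    def __init__(self, value, requires_grad: bool = False,
                 parents=(), bwd=None):
        self.v = np.asarray(value, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._bwd = bwd if self.requires_grad else None

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.v.shape

    @property
    def ndim(self):
        return self.v.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.v.copy())

    # ------------------------------------------------------------------
    def backward(self):
        if self.v.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative topological sort (graphs can be deep)
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.v)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None or node._bwd is None:
                if node.requires_grad and node._bwd is None and g is not None:
                    node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._bwd(g)):
                if not parent.requires_grad:
                    continue
                if pg is None:
                    continue
                acc = grads.get(id(parent))
                grads[id(parent)] = pg if acc is None else acc + pg
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
        # leaves collected during the loop above; also flush remaining
        for node in topo:
            if node._bwd is None and node.requires_grad:
                g = grads.pop(id(node), None)
                if g is not None:
                    node.grad = g if node.grad is None else node.grad + g

    # ------------------------------------------------------------------
    # arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        a, b = self, other
        return Tensor(a.v + b.v, parents=(a, b),
                      bwd=lambda g: (_unbroadcast(g, a.v.shape),
                                     _unbroadcast(g, b.v.shape)))

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor(-a.v, parents=(a,), bwd=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self, other
        return Tensor(a.v * b.v, parents=(a, b),
                      bwd=lambda g: (_unbroadcast(g * b.v, a.v.shape),
                                     _unbroadcast(g * a.v, b.v.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        a, b = self, other
        return Tensor(a.v / b.v, parents=(a, b),
                      bwd=lambda g: (_unbroadcast(g / b.v, a.v.shape),
                                     _unbroadcast(-g * a.v / b.v ** 2,
                                                  b.v.shape)))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, n: float):
        a = self
        return Tensor(a.v ** n, parents=(a,),
                      bwd=lambda g: (g * n * a.v ** (n - 1),))

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bwd(g):
            ga = np.matmul(g, np.swapaxes(b.v, -1, -2))
            gb = np.matmul(np.swapaxes(a.v, -1, -2), g)
            return (_unbroadcast(ga, a.v.shape), _unbroadcast(gb, b.v.shape))

        return Tensor(np.matmul(a.v, b.v), parents=(a, b), bwd=bwd)

    # ------------------------------------------------------------------
    # shape ops
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        return Tensor(a.v.reshape(shape), parents=(a,),
                      bwd=lambda g: (g.reshape(a.v.shape),))

    def transpose(self, *axes):
        a = self
        if not axes:
            axes = tuple(reversed(range(a.ndim)))
        inv = np.argsort(axes)
        return Tensor(a.v.transpose(axes), parents=(a,),
                      bwd=lambda g: (g.transpose(inv),))

    def __getitem__(self, idx):
        a = self

        def bwd(g):
            out = np.zeros_like(a.v)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor(a.v[idx], parents=(a,), bwd=bwd)

    # ------------------------------------------------------------------
    # reductions
    def sum(self, axis=None, keepdims=False):
        a = self

        def bwd(g):
            if axis is None:
                return (np.broadcast_to(g, a.v.shape).copy(),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            return (np.broadcast_to(gg, a.v.shape).copy(),)

        return Tensor(a.v.sum(axis=axis, keepdims=keepdims),
                      parents=(a,), bwd=bwd)

    def mean(self, axis=None, keepdims=False):
        a = self
        if axis is None:
            n = a.v.size
        elif isinstance(axis, tuple):
            n = int(np.prod([a.v.shape[ax] for ax in axis]))
        else:
            n = a.v.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------------
    # elementwise nonlinearities
    def exp(self):
        a = self
        out_v = np.exp(a.v)
        return Tensor(out_v, parents=(a,), bwd=lambda g: (g * out_v,))

    def log(self):
        a = self
        return Tensor(np.log(a.v), parents=(a,), bwd=lambda g: (g / a.v,))

    def sqrt(self):
        return self ** 0.5

    def sigmoid(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-a.v))
        return Tensor(s, parents=(a,), bwd=lambda g: (g * s * (1 - s),))

    def tanh(self):
        a = self
        t = np.tanh(a.v)
        return Tensor(t, parents=(a,), bwd=lambda g: (g * (1 - t * t),))

    def relu(self):
        a = self
        m = a.v > 0
        return Tensor(a.v * m, parents=(a,), bwd=lambda g: (g * m,))

    def softplus(self):
        """log(1 + exp(x)), numerically stable."""
        a = self
        out = np.logaddexp(0.0, a.v)
        s = 1.0 / (1.0 + np.exp(-a.v))
        return Tensor(out, parents=(a,), bwd=lambda g: (g * s,))

    # ------------------------------------------------------------------
    # composite ops with dedicated backward passes
    def softmax(self, axis=-1):
        a = self
        z = a.v - a.v.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            return (s * (g - dot),)

        return Tensor(s, parents=(a,), bwd=bwd)

    def log_softmax(self, axis=-1):
        a = self
        z = a.v - a.v.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out = z - lse
        s = np.exp(out)

        def bwd(g):
            return (g - s * g.sum(axis=axis, keepdims=True),)

        return Tensor(out, parents=(a,), bwd=bwd)

    def layernorm(self, eps: float = 1e-5):
        """Normalize over the last axis (no learned scale/shift here)."""
        a = self
        mu = a.v.mean(axis=-1, keepdims=True)
        xc = a.v - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        out = xc * inv
        n = a.v.shape[-1]

        def bwd(g):
            gmean = g.mean(axis=-1, keepdims=True)
            gx = (g - gmean - out * (g * out).mean(axis=-1, keepdims=True))
            return (gx * inv,)

        return Tensor(out, parents=(a,), bwd=bwd)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis=-1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.v.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(np.concatenate([t.v for t in tensors], axis=axis),
                  parents=tuple(tensors), bwd=bwd)


def stack(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]

    def bwd(g):
        return tuple(np.moveaxis(g, axis, 0))

    return Tensor(np.stack([t.v for t in tensors], axis=axis),
                  parents=tuple(tensors), bwd=bwd)


def conv3x3(x: Tensor, w: Tensor) -> Tensor:
    """2D convolution with 3x3 kernel and same zero padding.

    x: (H, W, Cin); w: (3, 3, Cin, Cout) -> (H, W, Cout).

    Implemented as a sum over the nine kernel offsets, which keeps both the
    forward and the backward pass as plain numpy tensordots (fast enough for
    the pair-map sizes used here, L <= a few hundred).
    """
    x = as_tensor(x)
    w = as_tensor(w)
    H, W, Cin = x.v.shape
    xp = np.pad(x.v, ((1, 1), (1, 1), (0, 0)))
    out = np.zeros((H, W, w.v.shape[3]))
    for dy in range(3):
        for dx in range(3):
            out += np.tensordot(xp[dy:dy + H, dx:dx + W], w.v[dy, dx],
                                axes=([2], [0]))

    def bwd(g):
        gx = np.zeros_like(xp)
        gw = np.zeros_like(w.v)
        for dy in range(3):
            for dx in range(3):
                gx[dy:dy + H, dx:dx + W] += np.tensordot(
                    g, w.v[dy, dx], axes=([2], [1]))
                gw[dy, dx] = np.tensordot(
                    xp[dy:dy + H, dx:dx + W], g, axes=([0, 1], [0, 1]))
        return (gx[1:1 + H, 1:1 + W], gw)

    return Tensor(out, parents=(x, w), bwd=bwd)
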