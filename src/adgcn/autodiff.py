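"""Minimal reverse-mode automatic differentiation over numpy arrays.

The network in :mod:`adgcn.model` is small (a handful of dense matrix
products and a sparse aggregation per layer), so a compact tape-based
autodiff engine is all that is needed to train it.  Only the operations
the model actually uses are implemented: broadcast add/multiply, dense
and sparse matrix products, ReLU, sigmoid, means, batch normalization,
dropout, row softmax and masked cross-entropy.

All arrays are float64.  Gradients accumulate into ``Tensor.grad`` during
``backward()`` via a topological sweep of the tape.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "relu",
    "sigmoid",
    "mean_rows",
    "spmm",
    "batch_norm",
    "batch_norm_inference",
    "dropout",
    "softmax_rows",
    "cross_entropy_probs",
    "sum_squares",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus a gradient slot and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # -- bookkeeping ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def backward(self) -> None:
        """Accumulate gradients of this (scalar) tensor w.r.t. the tape."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not isinstance(t, Tensor):
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g: np.ndarray) -> None:
        # Taking ownership of g is safe: backward closures never hand the
        # same array object to two different tensors (see __add__).
        if self.grad is None:
            self.grad = g if g.dtype == np.float64 else g.astype(np.float64)
        else:
            self.grad += g

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def bw(g):
            ga = _unbroadcast(g, self.data.shape)
            gb = _unbroadcast(g, other.data.shape)
            if gb is ga and other is not self:
                gb = gb.copy()  # never alias one gradient into two tensors
            self._accum(ga)
            other._accum(gb)

        return Tensor(out_data, True, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor(-self.data, True, (self,), bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, True, (self, other), bw)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data
        out_data = a @ b

        def bw(g):
            if b.ndim == 1:  # (m,n) @ (n,) -> (m,)
                self._accum(np.outer(g, b))
                other._accum(a.T @ g)
            else:
                self._accum(g @ b.T)
                other._accum(a.T @ g)

        return Tensor(out_data, True, (self, other), bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0

    def bw(g):
        x._accum(g * mask)

    return Tensor(x.data * mask, True, (x,), bw)


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    s = 1.0 / (1.0 + np.exp(-x.data))

    def bw(g):
        x._accum(g * s * (1.0 - s))

    return Tensor(s, True, (x,), bw)


def mean_rows(x: Tensor) -> Tensor:
    """Mean over axis 0: (N, C) -> (C,).  The SE squeeze."""
    x = as_tensor(x)
    n = x.data.shape[0]

    def bw(g):
        x._accum(np.broadcast_to(g / n, x.data.shape))

    return Tensor(x.data.mean(axis=0), True, (x,), bw)


def spmm(S, x: Tensor) -> Tensor:
    """Sparse constant matrix times tensor: ``S @ x``.

    ``S`` is a scipy sparse matrix treated as a constant of the graph.
    """
    x = as_tensor(x)
    out_data = S @ x.data

    def bw(g):
        x._accum(S.T @ g)

    return Tensor(out_data, True, (x,), bw)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Per-channel normalization over the N graph nodes (training mode).

    Returns ``(y, mu, var)`` with the batch statistics as plain arrays so
    the caller can maintain running estimates.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    n = x.data.shape[0]
    mu = x.data.mean(axis=0)
    xc = x.data - mu
    var = (xc * xc).mean(axis=0)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv_std
    y = gamma.data * xhat + beta.data

    def bw(g):
        gamma._accum((g * xhat).sum(axis=0))
        beta._accum(g.sum(axis=0))
        gx = g * gamma.data
        # standard fused batch-norm backward
        dx = (inv_std / n) * (
            n * gx - gx.sum(axis=0) - xhat * (gx * xhat).sum(axis=0)
        )
        x._accum(dx)

    return Tensor(y, True, (x, gamma, beta), bw), mu, var


def batch_norm_inference(x: Tensor, gamma: Tensor, beta: Tensor,
                         running_mean: np.ndarray, running_var: np.ndarray,
                         eps: float = 1e-5) -> Tensor:
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    inv_std = 1.0 / np.sqrt(running_var + eps)
    xhat_scale = inv_std  # constant w.r.t. x
    y = gamma.data * (x.data - running_mean) * inv_std + beta.data

    def bw(g):
        gamma._accum((g * (x.data - running_mean) * inv_std).sum(axis=0))
        beta._accum(g.sum(axis=0))
        x._accum(g * gamma.data * xhat_scale)

    return Tensor(y, True, (x, gamma, beta), bw)


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout with a seeded mask; identity when rate == 0."""
    x = as_tensor(x)
    if rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.data.shape) < keep) / keep

    def bw(g):
        x._accum(g * mask)

    return Tensor(x.data * mask, True, (x,), bw)


def softmax_rows(x: Tensor) -> Tensor:
    x = as_tensor(x)
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)

    def bw(g):
        x._accum(p * (g - (g * p).sum(axis=1, keepdims=True)))

    return Tensor(p, True, (x,), bw)


def cross_entropy_probs(Z: Tensor, labels: np.ndarray, mask: np.ndarray,
                        clamp: float = 1e-12) -> Tensor:
    """Mean of -log Z[i, labels[i]] over the vertices where ``mask`` is True."""
    Z = as_tensor(Z)
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise ValueError("no labeled vertices in cross-entropy")
    picked = np.clip(Z.data[idx, labels[idx]], clamp, None)
    loss = -np.log(picked).mean()

    def bw(g):
        dz = np.zeros_like(Z.data)
        dz[idx, labels[idx]] = -g / (picked * idx.size)
        Z._accum(dz)

    return Tensor(loss, True, (Z,), bw)


def sum_squares(x: Tensor) -> Tensor:
    x = as_tensor(x)

    def bw(g):
        x._accum(2.0 * g * x.data)

    return Tensor((x.data ** 2).sum(), True, (x,), bw)
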