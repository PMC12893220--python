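"""Compact reverse-mode automatic differentiation over numpy arrays.

Implements exactly the primitives the graph autoencoder needs: dense
and sparse-constant matrix products, broadcasting arithmetic, the
activation functions, and the special functions of the zero-inflated
negative binomial likelihood (lgamma with a digamma gradient,
numerically stable logaddexp / softplus). Gradients are accumulated by
topological sweep from any scalar output.
"""
from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.special import digamma, expit, gammaln


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient slot and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def item(self) -> float:
        return float(self.data)

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("divide by a Tensor via explicit reciprocal")
        return mul(self, 1.0 / np.asarray(other, dtype=float))

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    live = tuple(p for p in parents if isinstance(p, Tensor))
    out._parents = live
    out.requires_grad = any(p.requires_grad for p in live) or any(
        p._parents for p in live
    )
    out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray):
    g = _unbroadcast(np.asarray(g), t.data.shape)
    t.grad = g if t.grad is None else t.grad + g


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        _accum(a, g)
        _accum(b, g)

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        _accum(a, g * b.data)
        _accum(b, g * a.data)

    return _make(out_data, (a, b), backward)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    return _make(out_data, (a, b), backward)


def spmm(A: sp.spmatrix, x) -> Tensor:
    """Sparse constant matrix times dense Tensor."""
    x = as_tensor(x)
    At = A.T.tocsr()
    out_data = A @ x.data

    def backward(g):
        _accum(x, At @ g)

    return _make(out_data, (x,), backward)


def transpose(a) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        _accum(a, g.T)

    return _make(a.data.T, (a,), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0

    def backward(g):
        _accum(a, g * mask)

    return _make(a.data * mask, (a,), backward)


def tanh(a) -> Tensor:
    a = as_tensor(a)
    t = np.tanh(a.data)

    def backward(g):
        _accum(a, g * (1.0 - t * t))

    return _make(t, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    s = expit(a.data)

    def backward(g):
        _accum(a, g * s * (1.0 - s))

    return _make(s, (a,), backward)


def softplus(a) -> Tensor:
    """log(1 + exp(a)), overflow-safe."""
    a = as_tensor(a)
    out_data = np.logaddexp(0.0, a.data)
    s = expit(a.data)

    def backward(g):
        _accum(a, g * s)

    return _make(out_data, (a,), backward)


def exp(a) -> Tensor:
    a = as_tensor(a)
    e = np.exp(a.data)

    def backward(g):
        _accum(a, g * e)

    return _make(e, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        _accum(a, g / a.data)

    return _make(np.log(a.data), (a,), backward)


def lgamma(a) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        _accum(a, g * digamma(a.data))

    return _make(gammaln(a.data), (a,), backward)


def logaddexp(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = np.logaddexp(a.data, b.data)
    wa = expit(a.data - b.data)

    def backward(g):
        _accum(a, g * wa)
        _accum(b, g * (1.0 - wa))

    return _make(out_data, (a, b), backward)


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(g, a.data.shape))

    return _make(out_data, (a,), backward)


def tmean(a, axis=None) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis=axis), 1.0 / n)


ACTIVATIONS = {"relu": relu, "tanh": tanh, "sigmoid": sigmoid, "identity": lambda x: x}


class Adam:
    """Standard Adam with bias correction, full-batch."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def bce_logits_mean(Z: Tensor, targets: np.ndarray,
                    pos_weight: float | None = None) -> Tensor:
    """Mean binary cross-entropy with logits against constant targets.

    Fused single node: forward mean(softplus(z) - z * y), backward
    (sigmoid(z) - y) / N. Numerically safe for large |z|. With
    ``pos_weight`` w, positive targets are up-weighted:
    w * y * softplus(-z) + (1 - y) * softplus(z).
    """
    Z = as_tensor(Z)
    y = np.asarray(targets, dtype=float)
    z = Z.data
    if pos_weight is None:
        loss = float((np.logaddexp(0.0, z) - z * y).mean())

        def backward(g):
            _accum(Z, g * (expit(z) - y) / z.size)

    else:
        # pos_weight = n_neg/n_pos with the matching normalization keeps
        # the loss at the scale of an ordinary per-class mean:
        # 0.5 * (mean over positives + mean over negatives)
        w = pos_weight
        scale = 1.0 / (2.0 * max((1.0 - y).sum(), 1.0))
        loss = float(
            scale * (w * y * np.logaddexp(0.0, -z)
                     + (1.0 - y) * np.logaddexp(0.0, z)).sum()
        )

        def backward(g):
            _accum(
                Z,
                g * scale * ((1.0 - y) * expit(z) - w * y * expit(-z)),
            )

    return _make(loss, (Z,), backward)


def zinb_log_pmf(x: np.ndarray, pi_logit: Tensor, log_mu: Tensor,
                 log_theta: Tensor) -> Tensor:
    """Elementwise log-pmf of the zero-inflated negative binomial.

    Fused node with hand-derived gradients w.r.t. the dropout logit,
    log-mean and log-dispersion:

        log NB(x) = lgamma(x + th) - lgamma(th) - lgamma(x + 1)
                    + th (log th - log(th + mu)) + x (log mu - log(th + mu))
        pmf       = pi 1[x = 0] + (1 - pi) NB(x)

    evaluated in log space with logaddexp at the zeros.
    """
    pl, lm, lt = as_tensor(pi_logit), as_tensor(log_mu), as_tensor(log_theta)
    x = np.asarray(x, dtype=float)
    th = np.exp(np.broadcast_to(lt.data, x.shape))
    mu = np.exp(lm.data)
    ltm = np.logaddexp(np.broadcast_to(lt.data, x.shape), lm.data)
    lnb = (
        gammaln(x + th) - gammaln(th) - gammaln(x + 1.0)
        + th * (np.broadcast_to(lt.data, x.shape) - ltm)
        + x * (lm.data - ltm)
    )
    log1mpi = -np.logaddexp(0.0, pl.data)
    logpi = -np.logaddexp(0.0, -pl.data)
    lp_nonzero = log1mpi + lnb
    lp_zero = np.logaddexp(logpi, lp_nonzero)
    zero = x == 0
    out_data = np.where(zero, lp_zero, lp_nonzero)

    w_pi = expit(logpi - lp_nonzero)  # point-mass branch weight at x = 0
    sig = expit(pl.data)
    nb_w = np.where(zero, 1.0 - w_pi, 1.0)

    def backward(g):
        _accum(pl, g * np.where(zero, w_pi - sig, -sig))
        dlm = x - mu * (x + th) / (mu + th)
        _accum(lm, g * nb_w * dlm)
        dlt = th * (
            digamma(x + th) - digamma(th)
            + np.broadcast_to(lt.data, x.shape) - ltm
            + 1.0 - (th + x) / (th + mu)
        )
        _accum(lt, g * nb_w * dlt)

    return _make(out_data, (pl, lm, lt), backward)
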