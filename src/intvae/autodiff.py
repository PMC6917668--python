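"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the integrative-VAE architectures need:
affine maps, element-wise nonlinearities (ELU, sigmoid, exp, log, sqrt),
broadcast arithmetic, reductions, concatenation/slicing and transposition.
Gradients are accumulated by a topological backward sweep; broadcasting is
undone by summing gradients over the broadcast axes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "affine", "batchnorm_train",
           "mse_loss", "sigmoid_bce_loss", "kl_gaussian_node", "mmd_node",
           "reparam_node", "dropout_node"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = _prev

    # -- graph plumbing -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed recursion depth
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
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd(g):
            if self.requires_grad or self._prev:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._prev:
                other._accum(_unbroadcast(g, other.data.shape))
        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd(g):
            if self.requires_grad or self._prev:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._prev:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))

        def bwd(g):
            self._accum(g * p * self.data ** (p - 1.0))
        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd(g):
            if self.requires_grad or self._prev:
                self._accum(g @ other.data.T)
            if other.requires_grad or other._prev:
                other._accum(self.data.T @ g)
        out._backward = bwd
        return out

    # -- nonlinearities ---------------------------------------------------

    def exp(self):
        out = Tensor(np.exp(self.data), self.requires_grad, (self,))

        def bwd(g):
            self._accum(g * out.data)
        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def bwd(g):
            self._accum(g / self.data)
        out._backward = bwd
        return out

    def sqrt(self):
        return self ** 0.5

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, self.requires_grad, (self,))

        def bwd(g):
            self._accum(g * s * (1.0 - s))
        out._backward = bwd
        return out

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        e = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out = Tensor(np.where(pos, self.data, e), self.requires_grad, (self,))

        def bwd(g):
            self._accum(g * np.where(pos, 1.0, e + alpha))
        out._backward = bwd
        return out

    def clip(self, lo: float, hi: float):
        """Clip values; gradient passes only through the interior."""
        inside = (self.data > lo) & (self.data < hi)
        out = Tensor(np.clip(self.data, lo, hi), self.requires_grad, (self,))

        def bwd(g):
            self._accum(g * inside)
        out._backward = bwd
        return out

    # -- reductions / shaping ---------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    @property
    def T(self):
        out = Tensor(self.data.T, self.requires_grad, (self,))

        def bwd(g):
            self._accum(g.T)
        out._backward = bwd
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], self.requires_grad, (self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            full[key] = g
            self._accum(full)
        out._backward = bwd
        return out


# ---------------------------------------------------------------------------
# fused operations: single graph nodes with hand-derived backward passes.
# These keep the per-step node count small, which matters because each node
# costs Python-level overhead during both passes.


def affine(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """x @ W + b as one node."""
    out = Tensor(x.data @ W.data + b.data, True, (x, W, b))

    def bwd(g):
        if x.requires_grad or x._prev:
            x._accum(g @ W.data.T)
        W._accum(x.data.T @ g)
        b._accum(g.sum(axis=0))
    out._backward = bwd
    return out


def batchnorm_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float):
    """Batch normalization (training mode) as one node.

    Returns (out, batch_mean, batch_var) with the biased batch variance.
    """
    mu = x.data.mean(axis=0)
    var = x.data.var(axis=0)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(gamma.data * xhat + beta.data, True, (x, gamma, beta))
    n = x.data.shape[0]

    def bwd(g):
        beta._accum(g.sum(axis=0))
        gamma._accum((g * xhat).sum(axis=0))
        if x.requires_grad or x._prev:
            dxhat = g * gamma.data
            dx = (inv / n) * (n * dxhat - dxhat.sum(axis=0)
                              - xhat * (dxhat * xhat).sum(axis=0))
            x._accum(dx)
    out._backward = bwd
    return out, mu, var


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean over all entries of (pred - target)^2, as one node."""
    diff = pred.data - target
    out = Tensor(np.mean(diff ** 2), True, (pred,))

    def bwd(g):
        pred._accum(g * (2.0 / diff.size) * diff)
    out._backward = bwd
    return out


def sigmoid_bce_loss(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean binary cross-entropy of sigmoid(logits) against soft targets.

    Fused for numerical stability: uses log(1+exp(-|l|)) and the exact
    gradient (sigmoid(l) - t) / N.
    """
    ld = logits.data
    # stable: max(l,0) - l*t + log(1+exp(-|l|))
    val = np.mean(np.maximum(ld, 0.0) - ld * target
                  + np.log1p(np.exp(-np.abs(ld))))
    out = Tensor(val, True, (logits,))
    p = 1.0 / (1.0 + np.exp(-ld))

    def bwd(g):
        logits._accum(g * (p - target) / ld.size)
    out._backward = bwd
    return out


def kl_gaussian_node(mu: Tensor, logvar: Tensor) -> Tensor:
    """Batch-mean KL( N(mu, e^logvar) || N(0,I) ) as one node."""
    ev = np.exp(logvar.data)
    n = mu.data.shape[0]
    val = 0.5 * np.sum(mu.data ** 2 + ev - 1.0 - logvar.data) / n
    out = Tensor(val, True, (mu, logvar))

    def bwd(g):
        mu._accum(g * mu.data / n)
        logvar._accum(g * 0.5 * (ev - 1.0) / n)
    out._backward = bwd
    return out


def mmd_node(z: Tensor, zp: np.ndarray, sigma: float) -> Tensor:
    """Biased Gaussian-kernel MMD between z and fixed prior draws zp."""
    zd = z.data
    n, m = zd.shape[0], zp.shape[0]
    s2 = sigma ** 2
    g2 = 1.0 / (2.0 * s2)

    def sqd(a, b):
        aa = np.sum(a * a, axis=1)[:, None]
        bb = np.sum(b * b, axis=1)[None, :]
        return np.maximum(aa + bb - 2.0 * a @ b.T, 0.0)

    kqq = np.exp(-g2 * sqd(zd, zd))
    kpp_mean = float(np.exp(-g2 * sqd(zp, zp)).mean())
    kqp = np.exp(-g2 * sqd(zd, zp))
    out = Tensor(kqq.mean() + kpp_mean - 2.0 * kqp.mean(), True, (z,))

    def bwd(g):
        # d/dz_i of the V-statistic; kernel grad is -k * (z_i - y)/sigma^2
        dz = (-2.0 / (n * n * s2)) * (zd * kqq.sum(axis=1)[:, None] - kqq @ zd)
        dz += (2.0 / (n * m * s2)) * (zd * kqp.sum(axis=1)[:, None] - kqp @ zp)
        z._accum(g * dz)
    out._backward = bwd
    return out


def reparam_node(mu: Tensor, logvar: Tensor, eps: np.ndarray) -> Tensor:
    """z = mu + exp(logvar/2) * eps as one node."""
    sd = np.exp(logvar.data * 0.5)
    out = Tensor(mu.data + sd * eps, True, (mu, logvar))

    def bwd(g):
        mu._accum(g)
        logvar._accum(g * 0.5 * sd * eps)
    out._backward = bwd
    return out


def dropout_node(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    keep = 1.0 - rate
    mask = (rng.random(x.data.shape) < keep) / keep
    out = Tensor(x.data * mask, True, (x,))

    def bwd(g):
        x._accum(g * mask)
    out._backward = bwd
    return out


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)

    def zero_grad(self):
        self.grad = None


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis),
                 any(t.requires_grad or t._prev for t in tensors), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad or t._prev:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])
    out._backward = bwd
    return out
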