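"""Dense building blocks and the Adam optimizer used by every architecture.

Hidden blocks follow the order dense -> batch-norm -> ELU -> dropout; batch
normalization keeps running moments for evaluation mode. All parameters are
initialized from an explicit :class:`numpy.random.Generator` so that a model
is a pure function of its seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import (Parameter, Tensor, affine, batchnorm_train,
                       dropout_node)

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Dense:
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        self.W = Parameter(glorot_uniform(rng, n_in, n_out))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return affine(x, self.W, self.b)

    @property
    def parameters(self):
        return [self.W, self.b]


class BatchNorm:
    """Feature-wise batch normalization with running statistics."""

    def __init__(self, n_features: int):
        self.gamma = Parameter(np.ones(n_features))
        self.beta = Parameter(np.zeros(n_features))
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        if train:
            out, mu, var = batchnorm_train(x, self.gamma, self.beta, _BN_EPS)
            self.running_mean = (_BN_MOMENTUM * self.running_mean
                                 + (1 - _BN_MOMENTUM) * mu)
            self.running_var = (_BN_MOMENTUM * self.running_var
                                + (1 - _BN_MOMENTUM) * var)
            return out
        xhat = (x.data - self.running_mean) / np.sqrt(self.running_var + _BN_EPS)
        return Tensor(self.gamma.data * xhat + self.beta.data)

    @property
    def parameters(self):
        return [self.gamma, self.beta]


class HiddenBlock:
    """dense -> batch-norm -> ELU -> dropout, the standard hidden stage."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int,
                 dropout: float):
        self.dense = Dense(rng, n_in, n_out)
        self.bn = BatchNorm(n_out)
        self.dropout = float(dropout)

    def __call__(self, x: Tensor, train: bool,
                 rng: np.random.Generator | None = None) -> Tensor:
        h = self.bn(self.dense(x), train).elu()
        if train and self.dropout > 0.0:
            h = dropout_node(h, self.dropout, rng)
        return h

    @property
    def parameters(self):
        return self.dense.parameters + self.bn.parameters


class Adam:
    """Adam optimizer with the exponential-decay rates of the reference setup."""

    def __init__(self, params: list[Parameter], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
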