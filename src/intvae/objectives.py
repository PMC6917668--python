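"""Loss components of the integrative-VAE objective.

The composite objective is

    L = sum_m recon_m + beta * R,

where ``recon_m`` is a per-modality reconstruction term (mean squared error
for continuous data, binary cross-entropy with soft targets for categorical
data) and ``R`` regularizes the encoding distribution q(z|x) toward the
standard-normal prior, either through the closed-form diagonal-Gaussian KL
divergence or through a kernel Maximum Mean Discrepancy (MMD) between
posterior samples and prior draws.

All reconstruction terms are reduced by the mean over samples *and*
features, so that ``beta`` is comparable across modalities of different
widths. Public functions here are plain NumPy; the training loop mirrors
them on the autodiff graph (see :mod:`intvae.models`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EPSILON", "GRID_BETAS", "RegularizerSpec", "ObjectiveValue",
    "mse_recon", "bce_recon", "kl_gaussian", "gaussian_kernel",
    "mmd_biased", "composite_objective",
]

#: probability clip for cross-entropy numerical safety
EPSILON = 1e-7

#: regularization weights swept in the hyperparameter grid
GRID_BETAS = (1, 10, 15, 25, 50, 100)


@dataclass(frozen=True)
class RegularizerSpec:
    """Which divergence regularizes the posterior, and how strongly.

    Parameters
    ----------
    kind : {"KL", "MMD"}
    beta : positive weight of the regularization term.
    kernel_sigma : Gaussian-kernel bandwidth sigma for MMD. ``None`` selects
        the default sigma^2 = latent_dim / 2 at the call site.
    """

    kind: str
    beta: float
    kernel_sigma: float | None = None

    def __post_init__(self):
        if self.kind not in ("KL", "MMD"):
            raise ValueError(f"unknown regularizer kind: {self.kind!r}")
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")
        if self.kernel_sigma is not None and self.kernel_sigma <= 0:
            raise ValueError("kernel_sigma must be positive")


@dataclass
class ObjectiveValue:
    """One evaluation of the composite objective, with its breakdown."""

    total: float
    recon_per_modality: dict[str, float] = field(default_factory=dict)
    regularizer: float = 0.0
    beta: float = 1.0


def mse_recon(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Mean squared error, averaged over all entries."""
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    return float(np.mean((x - x_hat) ** 2))


def bce_recon(t: np.ndarray, p: np.ndarray) -> float:
    """Binary cross-entropy with soft targets, averaged over all entries.

    Targets ``t`` may be any reals in [0,1] (label-smoothed ordinal states
    included); predictions ``p`` are clipped to [EPSILON, 1-EPSILON].
    """
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {p.shape}")
    if np.any(t < 0) or np.any(t > 1):
        raise ValueError("targets must lie in [0, 1]")
    p = np.clip(p, EPSILON, 1.0 - EPSILON)
    return float(np.mean(-(t * np.log(p) + (1.0 - t) * np.log(1.0 - p))))


def kl_gaussian(mu: np.ndarray, logvar: np.ndarray) -> float:
    """Closed-form KL( N(mu, diag(exp(logvar))) || N(0, I) ).

    For a matrix input (batch x latent) the per-sample KL is averaged over
    the batch; the sum runs over latent dimensions.
    """
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    logvar = np.atleast_2d(np.asarray(logvar, dtype=float))
    if mu.shape != logvar.shape:
        raise ValueError(f"shape mismatch: {mu.shape} vs {logvar.shape}")
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(logvar))):
        raise ValueError("non-finite posterior parameters")
    per_sample = 0.5 * np.sum(mu ** 2 + np.exp(logvar) - 1.0 - logvar, axis=1)
    return float(np.mean(per_sample))


def gaussian_kernel(z: np.ndarray, z_prime: np.ndarray, sigma: float) -> float:
    """Gaussian kernel k(z, z') = exp(-||z - z'||^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    z = np.asarray(z, dtype=float)
    z_prime = np.asarray(z_prime, dtype=float)
    if z.shape != z_prime.shape:
        raise ValueError(f"shape mismatch: {z.shape} vs {z_prime.shape}")
    return float(np.exp(-np.sum((z - z_prime) ** 2) / (2.0 * sigma ** 2)))


def _sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    aa = np.sum(a * a, axis=1)[:, None]
    bb = np.sum(b * b, axis=1)[None, :]
    return np.maximum(aa + bb - 2.0 * a @ b.T, 0.0)


def mmd_biased(zq: np.ndarray, zp: np.ndarray, sigma: float) -> float:
    """Biased (V-statistic) MMD^2 between sample sets with a Gaussian kernel.

    MMD = E_p[k] + E_q[k] - 2 E_{q,p}[k], each expectation estimated by the
    full double mean including diagonal terms, which guarantees
    nonnegativity and MMD(Z, Z) = 0 exactly.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    zq = np.atleast_2d(np.asarray(zq, dtype=float))
    zp = np.atleast_2d(np.asarray(zp, dtype=float))
    if zq.shape[1] != zp.shape[1]:
        raise ValueError(f"dimension mismatch: {zq.shape[1]} vs {zp.shape[1]}")
    g = 1.0 / (2.0 * sigma ** 2)
    kqq = np.exp(-g * _sq_dists(zq, zq)).mean()
    kpp = np.exp(-g * _sq_dists(zp, zp)).mean()
    kqp = np.exp(-g * _sq_dists(zq, zp)).mean()
    return float(kqq + kpp - 2.0 * kqp)


def default_mmd_sigma(latent_dim: int) -> float:
    """Bandwidth heuristic sigma = sqrt(latent_dim / 2)."""
    return float(np.sqrt(latent_dim / 2.0))


def composite_objective(recon_terms: dict[str, float], reg: RegularizerSpec,
                        reg_value: float) -> ObjectiveValue:
    """Assemble total = sum of reconstruction terms + beta * regularizer."""
    total = float(sum(recon_terms.values()) + reg.beta * reg_value)
    return ObjectiveValue(total=total, recon_per_modality=dict(recon_terms),
                          regularizer=float(reg_value), beta=float(reg.beta))
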