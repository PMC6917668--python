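"""The four integrative VAE architectures under one model/results contract.

Every architecture encodes aligned multi-modal inputs into a diagonal
Gaussian posterior q(z|x) = N(mu, diag(sigma^2)), samples z by the
reparameterization trick, and decodes per-modality reconstructions scored
with modality-appropriate losses. They differ in *where* integration
happens:

* ``CNC`` — modalities concatenated at the input; one shared encoder and a
  single combined reconstruction.
* ``X``   — one encoder branch per modality merged before the bottleneck;
  the decoder splits back into per-modality branches.
* ``MM``  — like X, but each branch's second encoder layer receives the
  concatenation of *all* branches' first-layer outputs, so information is
  exchanged before the bottleneck (one extra encoder layer).
* ``H``   — a low-level VAE per modality trained first; their posterior
  means are concatenated and compressed by a high-level VAE (two-stage
  training).

Usage follows the model/results idiom::

    model = IntegrativeVAE(specs, config)      # or XVAE / MMVAE / HVAE
    res = model.fit(matrices)                  # -> VAEResults
    emb = res.encode(matrices)                 # posterior means, n x ls
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import (Tensor, concat, kl_gaussian_node, mmd_node, mse_loss,
                       reparam_node, sigmoid_bce_loss)
from .data import ModalitySpec, MultiOmicDataset
from .nn import Adam, Dense, HiddenBlock
from .objectives import ObjectiveValue, RegularizerSpec, default_mmd_sigma

__all__ = [
    "NetworkConfig", "LatentPosterior", "VAEResults",
    "IntegrativeVAE", "CNCVAE", "XVAE", "MMVAE", "HVAE",
    "build_cnc_vae", "build_x_vae", "build_mm_vae", "build_h_vae",
    "train", "train_hierarchical", "encode", "sample_generative",
    "reparameterize",
]


@dataclass(frozen=True)
class NetworkConfig:
    """All hyperparameters of one grid cell.

    Defaults follow the reference training protocol: 150 epochs of Adam
    (lr 0.001, beta1 0.9, beta2 0.999), batch size 64, hidden dropout 0.2.
    """

    architecture: str = "X"
    latent_size: int = 64
    dense_size: int = 256
    regularizer: RegularizerSpec = field(
        default_factory=lambda: RegularizerSpec("MMD", 50.0))
    dropout: float = 0.2
    epochs: int = 150
    learning_rate: float = 0.001
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.architecture not in ("CNC", "X", "MM", "H"):
            raise ValueError(f"unknown architecture: {self.architecture!r}")


@dataclass
class LatentPosterior:
    """Per-sample mean and log-variance of q(z|x)."""

    mu: np.ndarray
    logvar: np.ndarray

    def __post_init__(self):
        if self.mu.shape != self.logvar.shape:
            raise ValueError("mu and logvar shapes disagree")
        if not (np.all(np.isfinite(self.mu)) and np.all(np.isfinite(self.logvar))):
            raise ValueError("non-finite posterior parameters")


def reparameterize(post: LatentPosterior, eps: np.ndarray) -> np.ndarray:
    """z = mu + exp(logvar/2) * eps (element-wise)."""
    eps = np.asarray(eps, dtype=float)
    if eps.shape != post.mu.shape:
        raise ValueError(f"eps shape {eps.shape} != mu shape {post.mu.shape}")
    return post.mu + np.exp(post.logvar / 2.0) * eps


def _as_matrices(data, specs: list[ModalitySpec]) -> list[np.ndarray]:
    if isinstance(data, MultiOmicDataset):
        return [data.matrices[s.name] for s in specs]
    mats = [np.asarray(m, dtype=float) for m in data]
    if len(mats) != len(specs):
        raise ValueError(f"expected {len(specs)} modalities, got {len(mats)}")
    for m, s in zip(mats, specs):
        if m.ndim != 2 or m.shape[1] != s.n_features:
            raise ValueError(f"modality {s.name!r}: expected width "
                             f"{s.n_features}, got shape {m.shape}")
    return mats


class VAEResults:
    """Fit results: the trained model, its loss trace and summaries."""

    def __init__(self, model: "IntegrativeVAE", loss_trace: list[ObjectiveValue]):
        self.model = model
        self.loss_trace = loss_trace

    def encode(self, data) -> np.ndarray:
        return self.model.encode(data)

    def reconstruct(self, data) -> list[np.ndarray]:
        return self.model.reconstruct(data)

    def sample(self, n: int, seed: int = 0) -> list[np.ndarray]:
        return self.model.sample_generative(n, seed)

    def summary(self) -> str:
        cfg = self.model.config
        first, last = self.loss_trace[0], self.loss_trace[-1]
        lines = [
            f"{type(self.model).__name__} fit results",
            "=" * 40,
            f"architecture     {cfg.architecture}",
            f"latent size      {cfg.latent_size}",
            f"dense size       {cfg.dense_size}",
            f"regularizer      {cfg.regularizer.kind} (beta={cfg.regularizer.beta:g})",
            f"epochs           {len(self.loss_trace)}",
            f"total loss       {first.total:.4f} -> {last.total:.4f}",
            f"regularizer term {first.regularizer:.4f} -> {last.regularizer:.4f}",
        ]
        for name, v in last.recon_per_modality.items():
            lines.append(f"{f'recon[{name}]':<17}{v:.4f}")
        return "\n".join(lines)


class IntegrativeVAE:
    """Base class: shared training loop, posterior heads and decoding.

    Subclasses define the encoder topology via ``_encode_graph`` and the
    decoder via ``_decode_graph``. Construction, mini-batch order, dropout
    masks, reparameterization noise and prior draws are all derived from
    ``config.seed``, so a fit is a pure function of (data, config).
    """

    n_encoder_hidden_layers: int = 1

    def __init__(self, specs: list[ModalitySpec], config: NetworkConfig):
        for s in specs:
            if s.n_features <= 0:
                raise ValueError(f"zero-width modality {s.name!r}")
        self.specs = list(specs)
        self.config = config
        self.fitted = False
        self.loss_trace: list[ObjectiveValue] = []
        ss = np.random.SeedSequence(config.seed)
        init_ss, self._train_ss = ss.spawn(2)
        self._build(np.random.default_rng(init_ss))

    # -- to be provided by subclasses ------------------------------------

    def _build(self, rng: np.random.Generator) -> None:
        raise NotImplementedError

    def _encode_graph(self, xs, train, rng):
        raise NotImplementedError

    def _decode_raw(self, z, train, rng):
        raise NotImplementedError

    def _decode_graph(self, z, train, rng):
        """Decoded outputs with the spec activations applied."""
        return [self._apply_activation(o, s)
                for o, s in zip(self._decode_raw(z, train, rng), self.specs)]

    @property
    def parameters(self):
        raise NotImplementedError

    # -- shared machinery --------------------------------------------------

    def _mmd_sigma(self) -> float:
        reg = self.config.regularizer
        return reg.kernel_sigma or default_mmd_sigma(self.config.latent_size)

    def _output_blocks(self, rng, n_in: int) -> list[Dense]:
        return [Dense(rng, n_in, s.n_features) for s in self.specs]

    @staticmethod
    def _apply_activation(out: Tensor, spec: ModalitySpec) -> Tensor:
        return out.sigmoid() if spec.output_activation == "sigmoid" else out

    def _recon_loss(self, x: np.ndarray, raw_out: Tensor,
                    spec: ModalitySpec) -> Tensor:
        """Loss from the pre-activation decoder output for one modality."""
        if spec.recon_loss == "squared-error":
            return mse_loss(raw_out, x)
        return sigmoid_bce_loss(raw_out, x)

    def _regularizer_graph(self, mu: Tensor, logvar: Tensor, z: Tensor,
                           rng: np.random.Generator) -> Tensor:
        reg = self.config.regularizer
        if reg.kind == "KL":
            return kl_gaussian_node(mu, logvar)
        # MMD between posterior samples and fresh prior draws
        zp = rng.standard_normal(z.shape)
        return mmd_node(z, zp, self._mmd_sigma())

    def _batch_objective(self, xs_batch: list[np.ndarray],
                         rng: np.random.Generator):
        """Forward pass on one mini-batch; returns (graph total, breakdown)."""
        mu, logvar = self._encode_graph(xs_batch, train=True, rng=rng)
        eps = rng.standard_normal(mu.shape)
        z = reparam_node(mu, logvar, eps)
        raw_outs = self._decode_raw(z, train=True, rng=rng)
        recon_terms = {}
        total = None
        for x, out, spec in zip(xs_batch, raw_outs, self.specs):
            term = self._recon_loss(x, out, spec)
            recon_terms[spec.name] = term
            total = term if total is None else total + term
        reg = self._regularizer_graph(mu, logvar, z, rng)
        beta = self.config.regularizer.beta
        total = total + beta * reg
        breakdown = ObjectiveValue(
            total=float(total.data),
            recon_per_modality={k: float(v.data) for k, v in recon_terms.items()},
            regularizer=float(reg.data) if isinstance(reg, Tensor) else float(reg),
            beta=beta)
        return total, breakdown

    def fit(self, data) -> VAEResults:
        """Train with Adam; returns a :class:`VAEResults`."""
        cfg = self.config
        xs = _as_matrices(data, self.specs)
        n = xs[0].shape[0]
        if any(x.shape[0] != n for x in xs):
            raise ValueError("modalities disagree on the number of samples")
        if cfg.batch_size > n:
            raise ValueError("batch_size exceeds the number of samples")
        rng = np.random.default_rng(self._train_ss)
        opt = Adam(self.parameters, lr=cfg.learning_rate,
                   beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)
        self.loss_trace = []
        for _ in range(cfg.epochs):
            perm = rng.permutation(n)
            tot = 0.0
            recon = {s.name: 0.0 for s in self.specs}
            reg_sum = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = perm[start:start + cfg.batch_size]
                total, br = self._batch_objective([x[idx] for x in xs], rng)
                self._check_finite(br)
                opt.zero_grad()
                total.backward()
                opt.step()
                w = len(idx) / n
                tot += w * br.total
                reg_sum += w * br.regularizer
                for k, v in br.recon_per_modality.items():
                    recon[k] += w * v
            self.loss_trace.append(ObjectiveValue(
                total=tot, recon_per_modality=recon,
                regularizer=reg_sum, beta=cfg.regularizer.beta))
        self.fitted = True
        return VAEResults(self, self.loss_trace)

    @staticmethod
    def _check_finite(br: ObjectiveValue) -> None:
        for name, v in [("regularizer", br.regularizer),
                        *br.recon_per_modality.items()]:
            if not np.isfinite(v):
                raise RuntimeError(f"non-finite loss in term {name!r}; "
                                   "aborting training")

    # -- inference ---------------------------------------------------------

    def _require_fitted(self):
        if not self.fitted:
            raise RuntimeError("model has not been fitted")

    def posterior(self, data) -> LatentPosterior:
        self._require_fitted()
        xs = _as_matrices(data, self.specs)
        mu, logvar = self._encode_graph(xs, train=False, rng=None)
        return LatentPosterior(mu=mu.data.copy(), logvar=logvar.data.copy())

    def encode(self, data) -> np.ndarray:
        """Deterministic embedding: the posterior means, shape n x ls."""
        return self.posterior(data).mu

    def reconstruct(self, data) -> list[np.ndarray]:
        """Decode from the posterior mean; one matrix per modality."""
        self._require_fitted()
        xs = _as_matrices(data, self.specs)
        mu, _ = self._encode_graph(xs, train=False, rng=None)
        outs = self._decode_graph(mu, train=False, rng=None)
        return [o.data.copy() for o in outs]

    def sample_generative(self, n: int, seed: int = 0) -> list[np.ndarray]:
        """Decode z ~ N(0, I); one matrix per modality."""
        self._require_fitted()
        if n <= 0:
            raise ValueError("n must be positive")
        z = np.random.default_rng(seed).standard_normal(
            (n, self.config.latent_size))
        outs = self._decode_graph(Tensor(z), train=False, rng=None)
        return [o.data.copy() for o in outs]


class CNCVAE(IntegrativeVAE):
    """Concatenated-input VAE: one shared encoder/decoder pair."""

    n_encoder_hidden_layers = 1

    def _build(self, rng):
        ds, ls = self.config.dense_size, self.config.latent_size
        d_total = sum(s.n_features for s in self.specs)
        self.enc = HiddenBlock(rng, d_total, ds, self.config.dropout)
        self.mu_head = Dense(rng, ds, ls)
        self.logvar_head = Dense(rng, ds, ls)
        self.dec = HiddenBlock(rng, ls, ds, self.config.dropout)
        self.out = Dense(rng, ds, d_total)
        self._slices = []
        a = 0
        for s in self.specs:
            self._slices.append((a, a + s.n_features))
            a += s.n_features

    def _encode_graph(self, xs, train, rng):
        x = Tensor(np.concatenate(xs, axis=1))
        h = self.enc(x, train, rng)
        return self.mu_head(h), self.logvar_head(h)

    def _decode_raw(self, z, train, rng):
        h = self.dec(z, train, rng)
        full = self.out(h)
        return [full[:, a:b] for a, b in self._slices]

    @property
    def parameters(self):
        return (self.enc.parameters + self.mu_head.parameters
                + self.logvar_head.parameters + self.dec.parameters
                + self.out.parameters)


class XVAE(IntegrativeVAE):
    """X-shaped VAE: per-modality branches merged before the bottleneck."""

    n_encoder_hidden_layers = 1

    def _build(self, rng):
        ds, ls = self.config.dense_size, self.config.latent_size
        self.enc_branches = [HiddenBlock(rng, s.n_features, ds,
                                         self.config.dropout)
                             for s in self.specs]
        merged = ds * len(self.specs)
        self.mu_head = Dense(rng, merged, ls)
        self.logvar_head = Dense(rng, merged, ls)
        self.dec_branches = [HiddenBlock(rng, ls, ds, self.config.dropout)
                             for _ in self.specs]
        self.outs = self._output_blocks(rng, ds)

    def _encode_graph(self, xs, train, rng):
        hs = [branch(Tensor(x), train, rng)
              for branch, x in zip(self.enc_branches, xs)]
        merged = concat(hs, axis=1)
        return self.mu_head(merged), self.logvar_head(merged)

    def _decode_raw(self, z, train, rng):
        return [out_layer(branch(z, train, rng))
                for branch, out_layer in zip(self.dec_branches, self.outs)]

    @property
    def parameters(self):
        ps = []
        for b in self.enc_branches + self.dec_branches:
            ps += b.parameters
        for d in self.outs:
            ps += d.parameters
        return ps + self.mu_head.parameters + self.logvar_head.parameters


class MMVAE(XVAE):
    """Mixed-modal VAE: branches exchange first-layer outputs.

    Each branch's second encoder layer consumes the concatenation of all
    branches' first-layer outputs — one extra encoder layer relative to
    the X-shaped design.
    """

    n_encoder_hidden_layers = 2

    def _build(self, rng):
        ds = self.config.dense_size
        super()._build(rng)
        merged = ds * len(self.specs)
        self.enc_second = [HiddenBlock(rng, merged, ds, self.config.dropout)
                           for _ in self.specs]

    def _encode_graph(self, xs, train, rng):
        hs = [branch(Tensor(x), train, rng)
              for branch, x in zip(self.enc_branches, xs)]
        shared = concat(hs, axis=1)
        gs = [second(shared, train, rng) for second in self.enc_second]
        merged = concat(gs, axis=1)
        return self.mu_head(merged), self.logvar_head(merged)

    @property
    def parameters(self):
        ps = super().parameters
        for b in self.enc_second:
            ps += b.parameters
        return ps


class _UnimodalVAE(CNCVAE):
    """Single-modality VAE used as an H-VAE building block."""


class HVAE(IntegrativeVAE):
    """Hierarchical VAE: low-level VAEs per modality feed a high-level VAE.

    Stage 1 trains one VAE per modality; stage 2 concatenates their frozen
    posterior means (unbounded reals) and trains a high-level VAE on them
    with a squared-error reconstruction. ``loss_trace`` is the high-level
    trace; low-level traces are kept on the sub-models.
    """

    n_encoder_hidden_layers = 2  # one low-level + one high-level stage

    def __init__(self, specs, config,
                 low_level_models: list[IntegrativeVAE] | None = None):
        self._given_low = low_level_models
        super().__init__(specs, config)

    def _build(self, rng):
        cfg = self.config
        ls = cfg.latent_size
        ss = np.random.SeedSequence(cfg.seed).spawn(len(self.specs) + 1)
        if self._given_low is not None:
            if len(self._given_low) != len(self.specs):
                raise ValueError("one low-level model per modality required")
            for m, s in zip(self._given_low, self.specs):
                if m.specs[0].n_features != s.n_features:
                    raise ValueError("low-level model trained on different specs")
            self.low_models = self._given_low
        else:
            # same architecture for each low-level VAE
            self.low_models = [
                _UnimodalVAE([s], replace(cfg, architecture="CNC",
                                          seed=int(child.generate_state(1)[0] % (2**31))))
                for s, child in zip(self.specs, ss[:-1])]
        high_spec = ModalitySpec(name="low-level-means", kind="continuous",
                                 n_features=ls * len(self.specs))
        self.high_model = _UnimodalVAE(
            [high_spec], replace(cfg, architecture="CNC",
                                 seed=int(ss[-1].generate_state(1)[0] % (2**31))))

    def _low_means(self, xs: list[np.ndarray]) -> np.ndarray:
        for m in self.low_models:
            if not m.fitted:
                raise RuntimeError("low-level models are untrained")
        return np.concatenate(
            [m.encode([x]) for m, x in zip(self.low_models, xs)], axis=1)

    def fit(self, data) -> VAEResults:
        xs = _as_matrices(data, self.specs)
        for model, x in zip(self.low_models, xs):
            if not model.fitted:
                model.fit([x])
        means = self._low_means(xs)
        self.high_model.fit([means])
        self.loss_trace = self.high_model.loss_trace
        self.fitted = True
        return VAEResults(self, self.loss_trace)

    def posterior(self, data) -> LatentPosterior:
        self._require_fitted()
        xs = _as_matrices(data, self.specs)
        return self.high_model.posterior([self._low_means(xs)])

    def reconstruct(self, data) -> list[np.ndarray]:
        self._require_fitted()
        xs = _as_matrices(data, self.specs)
        rec_means = self.high_model.reconstruct([self._low_means(xs)])[0]
        return self._decode_means(rec_means)

    def _decode_means(self, means: np.ndarray) -> list[np.ndarray]:
        ls = self.config.latent_size
        outs = []
        for k, m in enumerate(self.low_models):
            z = Tensor(means[:, k * ls:(k + 1) * ls])
            outs.append(m._decode_graph(z, train=False, rng=None)[0].data.copy())
        return outs

    def sample_generative(self, n: int, seed: int = 0) -> list[np.ndarray]:
        self._require_fitted()
        if n <= 0:
            raise ValueError("n must be positive")
        means = self.high_model.sample_generative(n, seed)[0]
        return self._decode_means(means)

    @property
    def parameters(self):
        ps = []
        for m in self.low_models:
            ps += m.parameters
        return ps + self.high_model.parameters

    @property
    def sub_models(self) -> list[IntegrativeVAE]:
        return list(self.low_models) + [self.high_model]


_ARCH = {"CNC": CNCVAE, "X": XVAE, "MM": MMVAE, "H": HVAE}


def _check_multi(specs):
    if len(specs) < 2:
        raise ValueError("integration requires at least two modalities")


def make_model(specs: list[ModalitySpec], config: NetworkConfig) -> IntegrativeVAE:
    """Instantiate the architecture named in ``config.architecture``."""
    _check_multi(specs)
    return _ARCH[config.architecture](specs, config)


def build_cnc_vae(specs, config) -> CNCVAE:
    _check_multi(specs)
    return CNCVAE(specs, replace(config, architecture="CNC"))


def build_x_vae(specs, config) -> XVAE:
    _check_multi(specs)
    return XVAE(specs, replace(config, architecture="X"))


def build_mm_vae(specs, config) -> MMVAE:
    _check_multi(specs)
    return MMVAE(specs, replace(config, architecture="MM"))


def build_h_vae(specs, config, low_level_models=None) -> HVAE:
    _check_multi(specs)
    return HVAE(specs, replace(config, architecture="H"),
                low_level_models=low_level_models)


def train(model: IntegrativeVAE, data, config: NetworkConfig | None = None
          ) -> IntegrativeVAE:
    """Train ``model`` on the given rows; returns the fitted model."""
    if config is not None and config != model.config:
        raise ValueError("config disagrees with the model's config")
    model.fit(data)
    return model


def train_hierarchical(specs, data, config: NetworkConfig) -> HVAE:
    """Two-stage H-VAE training: low-level VAEs first, then the high level."""
    model = build_h_vae(specs, config)
    model.fit(data)
    return model


def encode(model: IntegrativeVAE, data) -> np.ndarray:
    return model.encode(data)


def sample_generative(model: IntegrativeVAE, n: int, seed: int = 0):
    return model.sample_generative(n, seed)
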