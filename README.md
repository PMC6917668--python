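# intvae — integrative variational autoencoders for multi-omic data

`intvae` learns a single low-dimensional representation of patient samples
described by several heterogeneous views at once — for example bulk mRNA
expression (continuous, scaled to [0,1]), copy-number aberration calls
(ordinal integer states) and one-hot-encoded clinical variables. It is
aimed at computational-biology practitioners who want to compress and
integrate such aligned sample-by-feature tables before clustering,
classification or visualization, and at methodologists comparing ways of
wiring multi-modal autoencoders.

## The model

Each sample `x = (x₁, …, x_M)` (one block per modality) is assumed to be
generated from a shared latent variable `z ∈ ℝ^ls` with a standard-normal
prior. An encoder network outputs a diagonal-Gaussian posterior
`q(z|x) = N(μ(x), diag(σ²(x)))`, a sample `z = μ + σ ⊙ ε` is decoded into
per-modality reconstructions, and training minimizes

```
L = Σ_m recon_m(x_m, x̂_m) + β · R(q(z|x), N(0, I))
```

where `recon_m` is mean squared error for continuous blocks and binary
cross-entropy (with ordinal states label-smoothed into [0,1]) for
categorical blocks, and the regularizer `R` is either the closed-form KL
divergence or a Gaussian-kernel Maximum Mean Discrepancy
`MMD = E_p[k] + E_q[k] − 2E_{q,p}[k]`, `k(z,z′) = exp(−‖z−z′‖²/2σ²)`,
between posterior samples and prior draws.

Four architectures share one model contract (`encode` / `reconstruct` /
`sample`), differing in where integration happens:

| name | integration point |
|------|-------------------|
| CNC-VAE | modalities concatenated at the input; one shared network |
| X-VAE | per-modality branches merged just before the bottleneck |
| MM-VAE | branches additionally exchange first-layer outputs (one extra encoder layer) |
| H-VAE | per-modality low-level VAEs feed a high-level VAE (two-stage training) |

Hidden layers are dense → batch-norm → ELU → dropout(0.2); training uses
Adam (lr 0.001, β₁ 0.9, β₂ 0.999), batch size 64, 150 epochs by default.
Embedding quality is scored by the stratified 5-fold cross-validated
accuracy of Gaussian naive Bayes, an RBF SVM (C = 1.5, γ = 1/N_f) and a
random forest (50 trees, half the features per split) trained on the
embedding, against PCA and raw-data baselines. The whole stack — including
a small reverse-mode autodiff engine — runs on NumPy alone.

## Worked example

```python
import numpy as np
from intvae import (SyntheticSpec, generate_multiomic, NetworkConfig,
                    RegularizerSpec, make_model, make_stratified_folds,
                    cross_validated_accuracy, vae_embed_fn)
from intvae.evaluation import DownstreamSpec

# three aligned modalities driven by a shared 4-d latent mixture, 2 classes
ds, truth = generate_multiomic(SyntheticSpec(n_samples=500, seed=1))

cfg = NetworkConfig(architecture="X", latent_size=16, dense_size=128,
                    regularizer=RegularizerSpec("MMD", 50.0),
                    epochs=60, seed=0)
model = make_model(ds.specs, cfg)
res = model.fit(ds)
print(res.summary())

folds = make_stratified_folds(ds.labels["class"], 5, seed=42)
r = cross_validated_accuracy(vae_embed_fn(ds, cfg), ds.labels["class"],
                             folds, DownstreamSpec("gaussian-naive-bayes"))
print(f"mean 5-fold test accuracy: {r.mean_test:.3f}")
```

prints (abridged):

```
XVAE fit results
========================================
architecture     X
latent size      16
dense size       128
regularizer      MMD (beta=50)
epochs           60
total loss       7.7338 -> 2.1075
regularizer term 0.1023 -> 0.0258
recon[mrna]      0.0453
recon[cna]       0.5065
recon[clinical]  0.2667
mean 5-fold test accuracy: 0.948
```

The total loss falls as the three reconstruction terms and the β-weighted
MMD shrink; the 16-dimensional embedding then lets a naive Bayes
classifier recover the two latent classes with 94.8% test accuracy, close
to the Bayes ceiling of the generator (~97%).

The same workflows are available from the shell:

```bash
intvae simulate --out data/ --seed 1
intvae train    --data data/ --out run/ --architecture x --epochs 60
intvae grid     --data data/ --out grid/ --architecture x --betas 1,50
intvae evaluate --data data/ --out eval/ --architectures cnc,x --tsne
```

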