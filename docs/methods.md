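# Methods

## Model and objective

All four architectures are variational autoencoders over aligned
multi-modal inputs `x = (x₁, …, x_M)`. The encoder outputs a diagonal
Gaussian `q(z|x) = N(μ, diag(exp(logvar)))`; decoding goes through the
reparameterized sample `z = μ + exp(logvar/2) ⊙ ε`, `ε ~ N(0, I)`. The
objective is

    L = Σ_m recon_m + β · R

with per-modality reconstruction terms and a prior regularizer `R`:

* **Reconstruction.** Continuous modalities use mean squared error and a
  linear decoder output (targets already lie in [0,1]). Categorical
  modalities (ordinal copy-number states, one-hot clinical blocks) use
  binary cross-entropy against soft targets produced by label smoothing —
  the K ordered states are mapped to equally spaced positions
  `j/(K−1) ∈ [0,1]` — with a sigmoid decoder output. All reconstruction
  terms are reduced by the **mean over samples and features**, so β is
  comparable across modalities of different widths and across batch sizes.
* **KL.** Closed form per sample, `½ Σ_j (μ_j² + e^{logvar_j} − 1 −
  logvar_j)`, averaged over the batch.
* **MMD.** Biased V-statistic with a Gaussian kernel
  `k(z,z′) = exp(−‖z−z′‖²/2σ²)` between the batch's posterior samples and
  an equal number of fresh standard-normal draws. The biased estimator
  (diagonal terms included) guarantees `MMD ≥ 0` and `MMD(Z,Z) = 0`
  exactly. The bandwidth defaults to `σ² = ls/2`, a standard
  median-free heuristic for standard-normal-scale latents; it is
  configurable per `RegularizerSpec`.

During training the cross-entropy is evaluated in its fused
logit form `max(l,0) − l·t + log(1+e^{−|l|})` with exact gradient
`(sigmoid(l) − t)/N`, which is the numerically stable equivalent of
clipping probabilities to `[1e−7, 1−1e−7]` (the convention used by the
public `bce_recon` function).

## Architectures

Depth is deliberately moderate (two to four hidden stages along any
input-to-reconstruction path). One hidden stage is always
dense → batch-norm → ELU → dropout(0.2); the bottleneck heads (μ, logvar)
and the decoder output layers are plain affine maps, sigmoid-activated for
categorical modalities.

* **CNC** — concatenate modalities at the input; one shared hidden stage
  each side; the decoder's single output layer is sliced back into
  per-modality blocks so each block is scored with its own loss.
* **X** — one hidden branch per modality, concatenated (width `M·ds`)
  before the μ/logvar heads; the decoder mirrors this with per-modality
  branches from `z`.
* **MM** — like X, but each branch has a second hidden layer whose input
  is the concatenation of *all* branches' first-layer outputs; exactly one
  more encoder layer than X.
* **H** — one unimodal VAE per modality is trained first (same
  architecture each, latent size equal to the final `ls`); their posterior
  means are concatenated (width `M·ls`) and compressed by a high-level VAE
  whose reconstruction target is that concatenation, scored with squared
  error because low-level means are unbounded reals. `encode` returns the
  high-level posterior mean of the low-level means; generative sampling
  decodes prior draws through the high-level then the low-level decoders.

The whole network stack runs on an in-package reverse-mode autodiff
engine over NumPy arrays with fused nodes for the expensive operations
(affine, batch-norm, losses, KL, MMD, reparameterization); gradient
correctness is checked against central finite differences in the test
suite.

## Training protocol and determinism

Adam with learning rate 0.001, moment decays 0.9/0.999, batch size 64,
150 epochs by default; mini-batches are reshuffled every epoch; the final
short batch is kept. Batch normalization keeps running moments
(momentum 0.9) that are used at evaluation time, so `encode` is
deterministic and per-row independent. All randomness — weight
initialization (Glorot uniform), batch order, dropout masks,
reparameterization noise, MMD prior draws — derives from
`NetworkConfig.seed` through a `SeedSequence` tree, so a fit is a pure
function of (data, config) and is bit-reproducible on a single CPU
thread. A non-finite loss aborts training with the offending term named.

## Preprocessing and folds

Continuous features are min-max scaled per column; a constant column maps
to all zeros (kept, to preserve feature indexing). Ordinal categorical
states are label-smoothed as above. Numeric clinical columns are
quantile-discretized (default 5 bins, collapsing with a warning when
there are fewer distinct values) and one-hot encoded; categorical clinical
columns are one-hot encoded directly. Tables are inner-joined on sample
IDs and ordered lexicographically. Stratified k-fold assignments are pure
functions of (labels, n_folds, seed) — the default seed 42 is recorded in
every run manifest — and are shared across all methods being compared so
that every method sees identical splits.

## Evaluation harness

A representation is scored by per-fold train/test accuracy of a
downstream classifier; the representation is re-trained per fold on the
fold's training rows only (PCA likewise fit on training rows), which the
test suite verifies by corrupting test rows and checking trained
parameters are bit-identical. A `fit_once` mode trains one model on all
rows for parity with protocols that do not retrain per fold. The grid
sweep covers latent size {16,32,64} × dense size {128,256,512} ×
{KL,MMD} × β {1,10,15,25,50,100} — 108 configurations per architecture
and task — scored with Gaussian naive Bayes (no extra hyperparameters),
streamed to a TSV store and resumable. Configuration selection takes the
best mean test accuracy with ties broken toward the simpler model
(smaller latent, smaller dense, MMD before KL, smaller β). tSNE
visualization delegates to scikit-learn with a fixed random state.

## Synthetic data

The generator emulates a breast-cancer-cohort shape: a continuous
expression-like view, a 5-state ordinal copy-number-like view and a
one-hot clinical-like view, all driven by a shared latent factor
`h ∈ ℝ^k` drawn from a mixture of class-conditional unit-variance
Gaussians. Class means have norm `class_sep` (default 2); with two
classes they are antipodal along the diagonal so every latent coordinate
carries signal, giving a joint Bayes accuracy of about Φ(class_sep) ≈
0.977 at the defaults. Observations are `logistic(hW + ε)` for the
continuous view, fixed-threshold ordinal states of `hW + ε` for the
copy-number view and rank-quantile one-hot blocks for the clinical view;
loading matrices have unit-norm columns and `ε` is Gaussian with
`noise_sd` (default 0.1). `signal_split` assigns the first
`ceil(split·k)` latent coordinates to the first modality and the rest to
the others, so in the split-signal scenario each modality alone is
strictly less informative than the pair — the ground truth records `h`,
the class and the loadings so these ceilings can be checked directly.
Desk-scale defaults are n = 500 with widths (100, 100, 50), one tenth of
the full-cohort scale available via `SyntheticSpec.metabric_scale()`
(1980 × (1000, 1000, 350)).

What the generator does **not** emulate: gene–gene correlation beyond the
shared factors, batch effects, missingness, survival outcomes, or
realistic marginal distributions of clinical variables. Passing tests
therefore demonstrate that the architectures recover planted shared-latent
structure and that the harness is leak-free — not performance on any real
cohort.

## Problem sizes used in the checked results

The training-heavy checks run a 16-dimensional embedding with dense width
128 for 60 epochs (convergence is reached well before that at n = 500;
the 150-epoch default remains for production use), with three training
seeds and shared stratified 5-fold splits. Oracle checks use 50 random
MMD instances (n, m ≤ 20, d ≤ 8) against an O(n²) double sum and 20
Monte-Carlo KL comparisons at 10⁵ draws.

## Design choices where the design was open

* Reconstruction reduction is the mean (not sum) over features — see
  above; this makes β values comparable across modalities.
* MMD prior sample count equals the batch size, drawn fresh each step.
* The embedding handed to downstream classifiers is the posterior mean,
  never a sample, for deterministic evaluation.
* H-VAE low-level latent size equals the final latent size.
* Layer order within a hidden stage is dense → batch-norm → ELU →
  dropout.
* Constant columns scale to zero rather than being dropped.
* The categorical-to-[0,1] mapping is equal spacing over the ordered
  state list.

## Known limitations

* Single-CPU NumPy training: fine at desk scale (seconds to minutes per
  fit), not intended for GPU-scale corpora.
* The biased MMD estimator is conservative (nonnegative by construction)
  but upward-biased at small batch sizes.
* Batch normalization couples samples within a training batch, so
  per-sample losses are only defined at evaluation time via running
  moments.
* `evaluate`'s report uses plain classification accuracy; with strongly
  unbalanced labels a balanced metric would be more informative.
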