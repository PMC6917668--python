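"""Embedding-quality evaluation: CV harness, classifiers, baselines, grid.

The quality of a learned representation is measured by the stratified
cross-validated accuracy of standard classifiers trained on it: Gaussian
naive Bayes (the grid's tuning-free classifier), an RBF-kernel SVM
(C = 1.5, gamma = 1/N_f) and a random forest (50 trees, half the features
per split). Baselines are PCA on the concatenated data and the raw
(uncompressed) matrices, per modality and combined.

Representations are re-trained per fold on the training rows only, so no
test information leaks into the embedding; a ``fit_once`` mode that trains
a single representation on all rows is available for parity with laxer
protocols.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.manifold import TSNE
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .data import FoldAssignment, MultiOmicDataset, make_stratified_folds
from .models import NetworkConfig, make_model
from .objectives import GRID_BETAS, RegularizerSpec

__all__ = [
    "DownstreamSpec", "GridResult", "cross_validated_accuracy",
    "vae_embed_fn", "raw_embed_fn", "pca_embed_fn", "enumerate_grid",
    "run_config_grid", "select_configuration", "pca_baseline",
    "raw_baseline", "tsne_export",
]

GRID_LATENT_SIZES = (16, 32, 64)
GRID_DENSE_SIZES = (128, 256, 512)
GRID_REGULARIZERS = ("KL", "MMD")


@dataclass(frozen=True)
class DownstreamSpec:
    """A downstream classifier with the fixed reference hyperparameters."""

    classifier: str = "gaussian-naive-bayes"
    svm_C: float = 1.5
    rf_trees: int = 50
    rf_features_per_split: float = 0.5
    classifier_seed: int = 0

    def make(self, n_features: int):
        if self.classifier == "gaussian-naive-bayes":
            return GaussianNB()
        if self.classifier == "svm-rbf":
            # gamma = 1 / N_f
            return SVC(C=self.svm_C, kernel="rbf", gamma=1.0 / n_features)
        if self.classifier == "random-forest":
            return RandomForestClassifier(
                n_estimators=self.rf_trees,
                max_features=self.rf_features_per_split,
                random_state=self.classifier_seed)
        raise ValueError(f"unknown classifier: {self.classifier!r}")


@dataclass
class GridResult:
    config: NetworkConfig | None
    task: str
    train_accuracy: list[float] = field(default_factory=list)
    test_accuracy: list[float] = field(default_factory=list)

    @property
    def mean_train(self) -> float:
        return float(np.mean(self.train_accuracy))

    @property
    def mean_test(self) -> float:
        return float(np.mean(self.test_accuracy))


def cross_validated_accuracy(embed_fn, labels: np.ndarray,
                             folds: FoldAssignment,
                             spec: DownstreamSpec | None = None,
                             task: str = "class",
                             config: NetworkConfig | None = None) -> GridResult:
    """Per-fold train/test accuracy of a classifier on learned embeddings.

    ``embed_fn(train_rows, test_rows)`` must train the representation on
    the training rows only and return (train_embedding, test_embedding).
    """
    spec = spec or DownstreamSpec()
    y = np.asarray(labels)
    res = GridResult(config=config, task=task)
    for fold in range(folds.n_folds):
        tr, te = folds.train_rows(fold), folds.test_rows(fold)
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"fold {fold} has a single class in training")
        e_tr, e_te = embed_fn(tr, te)
        clf = spec.make(e_tr.shape[1])
        clf.fit(e_tr, y[tr])
        res.train_accuracy.append(float(np.mean(clf.predict(e_tr) == y[tr])))
        res.test_accuracy.append(float(np.mean(clf.predict(e_te) == y[te])))
    return res


# ---------------------------------------------------------------------------
# embedding providers


def vae_embed_fn(dataset: MultiOmicDataset, config: NetworkConfig,
                 fit_once: bool = False):
    """Embedding provider that trains an integrative VAE per fold.

    With ``fit_once`` a single model is trained on all rows up front; the
    default re-trains on each fold's training rows to rule out leakage.
    """
    if fit_once:
        model = make_model(dataset.specs, config)
        model.fit(dataset)

        def embed(train_rows, test_rows):
            return (model.encode(dataset.subset(train_rows)),
                    model.encode(dataset.subset(test_rows)))
    else:
        def embed(train_rows, test_rows):
            model = make_model(dataset.specs, config)
            model.fit(dataset.subset(train_rows))
            return (model.encode(dataset.subset(train_rows)),
                    model.encode(dataset.subset(test_rows)))
    return embed


def cached_embed_fn(embed_fn):
    """Memoize an embedding provider by fold rows (reuse across classifiers)."""
    cache: dict[bytes, tuple[np.ndarray, np.ndarray]] = {}

    def embed(train_rows, test_rows):
        key = np.asarray(train_rows).tobytes()
        if key not in cache:
            cache[key] = embed_fn(train_rows, test_rows)
        return cache[key]
    return embed


def raw_embed_fn(dataset: MultiOmicDataset,
                 modality_names: list[str] | None = None):
    x = raw_baseline(dataset, modality_names or [s.name for s in dataset.specs])

    def embed(train_rows, test_rows):
        return x[train_rows], x[test_rows]
    return embed


def pca_embed_fn(dataset: MultiOmicDataset, k: int = 64,
                 modality_names: list[str] | None = None):
    x = raw_baseline(dataset, modality_names or [s.name for s in dataset.specs])

    def embed(train_rows, test_rows):
        return pca_baseline(x[train_rows], x[test_rows], k)
    return embed


# ---------------------------------------------------------------------------
# hyperparameter grid


def enumerate_grid(architecture: str,
                   latent_sizes=GRID_LATENT_SIZES,
                   dense_sizes=GRID_DENSE_SIZES,
                   regularizers=GRID_REGULARIZERS,
                   betas=GRID_BETAS,
                   seed: int = 0, **overrides) -> list[NetworkConfig]:
    """Cartesian product of the hyperparameter axes, in lexicographic order."""
    configs = []
    for ls, ds, reg, beta in itertools.product(latent_sizes, dense_sizes,
                                               regularizers, betas):
        configs.append(NetworkConfig(
            architecture=architecture, latent_size=ls, dense_size=ds,
            regularizer=RegularizerSpec(reg, float(beta)), seed=seed,
            **overrides))
    if len(set(configs)) != len(configs):
        raise ValueError("duplicate configurations in the grid axes")
    return configs


def _config_key(cfg: NetworkConfig) -> str:
    return (f"{cfg.architecture}:ls={cfg.latent_size}:ds={cfg.dense_size}:"
            f"reg={cfg.regularizer.kind}:beta={cfg.regularizer.beta:g}")


def run_config_grid(architecture: str, task: str, dataset: MultiOmicDataset,
                    configs: list[NetworkConfig] | None = None,
                    folds: FoldAssignment | None = None,
                    store_path: str | Path | None = None,
                    fit_once: bool = False,
                    **axes) -> list[GridResult]:
    """Evaluate each grid configuration with Gaussian naive Bayes CV accuracy.

    Results stream to ``store_path`` (one TSV row per config+fold) as they
    complete; a rerun with the same store resumes, skipping finished cells.
    """
    configs = configs or enumerate_grid(architecture, **axes)
    if len({_config_key(c) for c in configs}) != len(configs):
        raise ValueError("duplicate configurations")
    folds = folds or make_stratified_folds(dataset.labels[task], task=task)
    y = dataset.labels[task]
    done: dict[str, GridResult] = {}
    store = Path(store_path) if store_path else None
    if store and store.exists():
        prev = pd.read_csv(store, sep="\t")
        for key, grp in prev.groupby("config"):
            grp = grp.sort_values("fold")
            done[key] = GridResult(config=None, task=task,
                                   train_accuracy=list(grp["train_accuracy"]),
                                   test_accuracy=list(grp["test_accuracy"]))
    results = []
    for cfg in configs:
        key = _config_key(cfg)
        if key in done:
            r = done[key]
            r.config = cfg
            results.append(r)
            continue
        r = cross_validated_accuracy(
            vae_embed_fn(dataset, cfg, fit_once=fit_once), y, folds,
            DownstreamSpec("gaussian-naive-bayes"), task=task, config=cfg)
        results.append(r)
        if store:
            rows = pd.DataFrame({
                "config": key, "architecture": cfg.architecture,
                "latent_size": cfg.latent_size, "dense_size": cfg.dense_size,
                "regularizer": cfg.regularizer.kind,
                "beta": cfg.regularizer.beta, "task": task,
                "fold": range(folds.n_folds),
                "train_accuracy": r.train_accuracy,
                "test_accuracy": r.test_accuracy,
            })
            rows.to_csv(store, sep="\t", mode="a", index=False,
                        header=not store.exists())
    return results


def select_configuration(results: list[GridResult]) -> NetworkConfig:
    """Configuration with the best mean test accuracy.

    Ties break toward the simpler model: smaller latent size, smaller dense
    size, MMD before KL, smaller beta.
    """
    if not results:
        raise ValueError("no grid results to select from")

    def sort_key(r: GridResult):
        c = r.config
        return (-r.mean_test, c.latent_size, c.dense_size,
                0 if c.regularizer.kind == "MMD" else 1, c.regularizer.beta)
    return min(results, key=sort_key).config


# ---------------------------------------------------------------------------
# baselines and visualization


def pca_baseline(train: np.ndarray, test: np.ndarray, k: int,
                 return_model: bool = False):
    """Project both partitions onto the top-k axes fit on the training rows."""
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    if k > min(train.shape):
        raise ValueError(f"k={k} exceeds min(n_train, d)={min(train.shape)}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(train), pca.transform(test)
    return (*scores, pca) if return_model else scores


def raw_baseline(dataset: MultiOmicDataset,
                 modality_names: list[str]) -> np.ndarray:
    """Column-concatenation of the selected preprocessed modalities."""
    if not modality_names:
        raise ValueError("modality subset must be nonempty")
    known = {s.name for s in dataset.specs}
    unknown = [m for m in modality_names if m not in known]
    if unknown:
        raise ValueError(f"unknown modality name(s): {unknown}")
    order = [s.name for s in dataset.specs if s.name in modality_names]
    return np.concatenate([dataset.matrices[m] for m in order], axis=1)


def tsne_export(embedding: np.ndarray, labels: np.ndarray,
                out_path: str | Path, seed: int = 0,
                figure: bool = True) -> pd.DataFrame:
    """2-D tSNE of an embedding, written as TSV (and a scatter figure).

    The projection itself is delegated to scikit-learn's implementation.
    """
    emb = np.asarray(embedding, dtype=float)
    if not np.all(np.isfinite(emb)):
        raise ValueError("non-finite embedding entries")
    if emb.shape[0] < 5:
        raise ValueError("need at least 5 samples for tSNE")
    perplexity = min(30.0, (emb.shape[0] - 1) / 3.0)
    coords = TSNE(n_components=2, random_state=seed, perplexity=perplexity,
                  init="pca").fit_transform(emb)
    out_path = Path(out_path)
    table = pd.DataFrame({"tsne1": coords[:, 0], "tsne2": coords[:, 1],
                          "label": np.asarray(labels)})
    table.to_csv(out_path, sep="\t", index=False)
    if figure:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 5))
        for lab in np.unique(table["label"]):
            sel = table["label"] == lab
            ax.scatter(table.loc[sel, "tsne1"], table.loc[sel, "tsne2"],
                       s=8, label=str(lab))
        ax.legend(title="class", fontsize=8)
        ax.set_xlabel("tSNE 1")
        ax.set_ylabel("tSNE 2")
        fig.tight_layout()
        fig.savefig(out_path.with_suffix(".png"), dpi=120)
        plt.close(fig)
    return table
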