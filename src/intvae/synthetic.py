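"""Synthetic multi-modal data with known shared-latent class structure.

Emulates the shapes and value ranges of a breast-cancer cohort with three
aligned views per sample: a continuous expression-like modality in [0,1],
an ordinal copy-number-like modality with a small number of integer states,
and a one-hot clinical-like block matrix. All views are driven by a shared
k-dimensional latent factor h drawn from a mixture of class-conditional
Gaussians, so the class is decodable from the latent space and — through
the loading matrices — partially from each modality.

``signal_split`` partitions the latent coordinates between modalities:
at 1.0 every modality loads on every coordinate; below 1.0 the first
modality sees only the first ``ceil(split*k)`` coordinates and the others
see the rest, making each modality alone strictly less informative than
the pair (the "integration benefit" scenario).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import cross_val_score
from sklearn.naive_bayes import GaussianNB

from .data import ModalitySpec, MultiOmicDataset, smooth_categorical

__all__ = ["SyntheticSpec", "GroundTruth", "generate_multiomic",
           "split_signal_scenario", "latent_bayes_accuracy",
           "observed_accuracy"]

#: ordinal state values mimicking copy-number calls
CNA_STATES = (-2, -1, 0, 1, 2)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters.

    Defaults are one tenth of the full cohort widths for desk-scale runs;
    ``metabric_scale()`` gives the full 1980 x (1000, 1000, 350) shapes.
    ``class_sep`` is the distance of each class mean from the origin in
    latent units (within-class standard deviation is 1), so two antipodal
    classes are ``2*class_sep`` apart.
    """

    n_samples: int = 500
    latent_rank: int = 4
    n_classes: int = 2
    d_continuous: int = 100
    d_categorical: int = 100
    d_clinical: int = 50
    signal_split: float = 1.0
    noise_sd: float = 0.1
    class_sep: float = 2.0
    n_states: int = 5
    clinical_bins: int = 5
    seed: int = 0

    def __post_init__(self):
        dims = (self.d_continuous, self.d_categorical, self.d_clinical)
        if self.latent_rank >= min(dims):
            raise ValueError("latent_rank must be smaller than every "
                             "modality dimension")
        if self.n_classes > self.n_samples / 10:
            raise ValueError("n_classes must be at most n_samples/10")
        if not 0 < self.signal_split <= 1:
            raise ValueError("signal_split must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @staticmethod
    def metabric_scale(**kw) -> "SyntheticSpec":
        defaults = dict(n_samples=1980, d_continuous=1000,
                        d_categorical=1000, d_clinical=350)
        defaults.update(kw)
        return SyntheticSpec(**defaults)


@dataclass
class GroundTruth:
    """Latent factors, class labels and loadings behind a generated dataset."""

    h: np.ndarray
    labels: np.ndarray
    class_means: np.ndarray
    loadings: dict[str, np.ndarray]
    visible_coords: dict[str, np.ndarray] = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.h, columns=[f"h{j}" for j in range(self.h.shape[1])])
        df.insert(0, "class", self.labels)
        return df


def _class_means(k: int, n_classes: int, class_sep: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Well-separated class means of norm ``class_sep`` in k dimensions.

    Two classes get antipodal means along the diagonal so every latent
    coordinate carries signal (needed for signal splitting); more classes
    get the best-separated of 64 seeded random unit-direction draws.
    """
    if n_classes == 2:
        u = np.ones(k) / np.sqrt(k)
        return class_sep * np.stack([u, -u])
    best, best_d = None, -1.0
    for _ in range(64):
        cand = rng.standard_normal((n_classes, k))
        cand /= np.linalg.norm(cand, axis=1, keepdims=True)
        d = np.inf
        for i in range(n_classes):
            for j in range(i + 1, n_classes):
                d = min(d, np.linalg.norm(cand[i] - cand[j]))
        if d > best_d:
            best, best_d = cand, d
    return class_sep * best


def _loadings(k: int, d: int, visible: np.ndarray,
              rng: np.random.Generator) -> np.ndarray:
    """k x d loading matrix, unit-norm columns, zero rows off `visible`."""
    w = np.zeros((k, d))
    if len(visible):
        w[visible] = rng.standard_normal((len(visible), d))
        w /= np.linalg.norm(w, axis=0, keepdims=True)
    return w


def _rank_onehot(col: np.ndarray, n_bins: int) -> np.ndarray:
    """Rank-quantile one-hot encoding with exactly n_bins columns."""
    n = len(col)
    ranks = np.argsort(np.argsort(col, kind="stable"), kind="stable")
    codes = ranks * n_bins // n
    out = np.zeros((n, n_bins))
    out[np.arange(n), codes] = 1.0
    return out


def generate_multiomic(spec: SyntheticSpec,
                       modalities: tuple[str, ...] = ("mrna", "cna", "clinical"),
                       ) -> tuple[MultiOmicDataset, GroundTruth]:
    """Draw one dataset; same spec (and seed) gives an identical dataset."""
    rng = np.random.default_rng(spec.seed)
    k, n = spec.latent_rank, spec.n_samples

    means = _class_means(k, spec.n_classes, spec.class_sep, rng)
    y = rng.integers(0, spec.n_classes, size=n)
    h = means[y] + rng.standard_normal((n, k))

    n_first = int(np.ceil(spec.signal_split * k))
    all_coords = np.arange(k)
    visible = {}
    for i, name in enumerate(modalities):
        if spec.signal_split >= 1.0:
            visible[name] = all_coords
        else:
            visible[name] = (all_coords[:n_first] if i == 0
                             else all_coords[n_first:])

    dims = {"mrna": spec.d_continuous, "cna": spec.d_categorical,
            "clinical": spec.d_clinical}
    specs, matrices, loadings = [], {}, {}
    for name in modalities:
        w = _loadings(k, dims[name], visible[name], rng)
        loadings[name] = w
        scores = h @ w + spec.noise_sd * rng.standard_normal((n, dims[name]))
        if name == "mrna":
            matrices[name] = 1.0 / (1.0 + np.exp(-scores))
            specs.append(ModalitySpec(name, "continuous", dims[name]))
        elif name == "cna":
            states = np.asarray(CNA_STATES[:spec.n_states])
            edges = np.linspace(-1.5, 1.5, spec.n_states - 1)
            raw = states[np.searchsorted(edges, scores)]
            matrices[name] = smooth_categorical(raw, list(states))
            specs.append(ModalitySpec(name, "categorical", dims[name]))
        else:
            n_blocks = dims[name] // spec.clinical_bins
            rem = dims[name] - n_blocks * spec.clinical_bins
            widths = [spec.clinical_bins] * n_blocks
            if rem >= 2:
                widths.append(rem)
            elif rem:
                widths[-1] += rem
            blocks = [_rank_onehot(scores[:, j], wdt)
                      for j, wdt in enumerate(widths)]
            matrices[name] = np.concatenate(blocks, axis=1)
            specs.append(ModalitySpec(name, "categorical", dims[name]))

    ids = [f"S{i:05d}" for i in range(n)]
    ds = MultiOmicDataset(sample_ids=ids, specs=specs, matrices=matrices,
                          labels={"class": y})
    gt = GroundTruth(h=h, labels=y, class_means=means, loadings=loadings,
                     visible_coords=visible)
    return ds, gt


def split_signal_scenario(spec: SyntheticSpec
                          ) -> tuple[MultiOmicDataset, GroundTruth]:
    """Two-modality dataset where neither modality alone is fully informative.

    The class-informative latent coordinates are partitioned between a
    continuous and a categorical modality according to ``signal_split``,
    so each single-modality Bayes accuracy is strictly below the joint one.
    """
    if not 0 < spec.signal_split < 1:
        raise ValueError("signal_split must lie strictly in (0, 1)")
    return generate_multiomic(spec, modalities=("mrna", "cna"))


def latent_bayes_accuracy(gt: GroundTruth, coords: np.ndarray | None = None,
                          n_folds: int = 5) -> float:
    """Cross-validated accuracy of a Gaussian classifier on the true factors.

    Restricting ``coords`` to one modality's visible coordinates estimates
    that modality's ceiling; all coordinates estimate the joint ceiling.
    """
    h = gt.h if coords is None else gt.h[:, coords]
    if h.shape[1] == 0:
        return float(np.bincount(gt.labels).max() / len(gt.labels))
    return float(cross_val_score(GaussianNB(), h, gt.labels, cv=n_folds).mean())


def observed_accuracy(dataset: MultiOmicDataset,
                      modality_names: list[str] | None = None,
                      task: str = "class", n_folds: int = 5) -> float:
    """Cross-validated Gaussian naive Bayes accuracy on observed matrices."""
    names = modality_names or [s.name for s in dataset.specs]
    x = np.concatenate([dataset.matrices[m] for m in names], axis=1)
    y = dataset.labels[task]
    return float(cross_val_score(GaussianNB(), x, y, cv=n_folds).mean())
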