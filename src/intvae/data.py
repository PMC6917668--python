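"""Domain types, preprocessing and stratified fold construction.

Modalities are sample-by-feature tables. Continuous features are min-max
scaled to [0,1]; ordinal categorical states (e.g. copy-number aberration
calls from deletion to amplification) are mapped to equally spaced soft
targets in [0,1] so that a Bernoulli cross-entropy can score them; numeric
clinical columns are quantile-discretized and one-hot encoded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ModalitySpec", "MultiOmicDataset", "FoldAssignment",
    "scale_minmax", "smooth_categorical", "discretize_and_onehot",
    "assemble_dataset", "make_stratified_folds",
]

DEFAULT_FOLD_SEED = 42


@dataclass(frozen=True)
class ModalitySpec:
    """Description of one data modality.

    ``kind`` is "continuous" (squared-error reconstruction, linear output)
    or "categorical" (cross-entropy reconstruction, sigmoid output).
    """

    name: str
    kind: str
    n_features: int
    recon_loss: str = ""
    output_activation: str = ""

    def __post_init__(self):
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown modality kind: {self.kind!r}")
        if self.n_features <= 0:
            raise ValueError("n_features must be positive")
        # derive loss/activation tags from the kind when not given
        if not self.recon_loss:
            object.__setattr__(self, "recon_loss",
                               "squared-error" if self.kind == "continuous"
                               else "cross-entropy")
        if not self.output_activation:
            object.__setattr__(self, "output_activation",
                               "linear" if self.kind == "continuous"
                               else "sigmoid")
        if self.kind == "categorical":
            if self.recon_loss != "cross-entropy" or self.output_activation != "sigmoid":
                raise ValueError("categorical modalities use cross-entropy "
                                 "loss and sigmoid output")
        if self.kind == "continuous" and self.recon_loss != "squared-error":
            raise ValueError("continuous modalities use squared-error loss")


@dataclass
class MultiOmicDataset:
    """Aligned per-modality matrices plus label vectors."""

    sample_ids: list[str]
    specs: list[ModalitySpec]
    matrices: dict[str, np.ndarray]
    labels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.sample_ids)
        for spec in self.specs:
            m = self.matrices[spec.name]
            if m.shape != (n, spec.n_features):
                raise ValueError(f"modality {spec.name!r} has shape {m.shape}, "
                                 f"expected {(n, spec.n_features)}")
            if m.size and (m.min() < 0 or m.max() > 1):
                raise ValueError(f"modality {spec.name!r} not in [0,1]")
        for task, y in self.labels.items():
            if len(y) != n:
                raise ValueError(f"label {task!r} has {len(y)} entries, expected {n}")
            if len(np.unique(y)) < 2:
                raise ValueError(f"label {task!r} has fewer than 2 classes")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def modality_list(self) -> list[np.ndarray]:
        return [self.matrices[s.name] for s in self.specs]

    def subset(self, rows: np.ndarray) -> "MultiOmicDataset":
        return MultiOmicDataset(
            sample_ids=[self.sample_ids[i] for i in rows],
            specs=self.specs,
            matrices={k: v[rows] for k, v in self.matrices.items()},
            labels={k: v[rows] for k, v in self.labels.items()},
        )


@dataclass
class FoldAssignment:
    task: str
    n_folds: int
    fold_of: np.ndarray
    seed: int

    def test_rows(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_rows(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)


# ---------------------------------------------------------------------------
# preprocessing operations


def scale_minmax(column: np.ndarray) -> np.ndarray:
    """Min-max scale a vector (or each column of a matrix) to [0,1].

    A constant column maps to all zeros, preserving feature indexing.
    """
    x = np.asarray(column, dtype=float)
    if x.size == 0:
        raise ValueError("cannot scale an empty column")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in column")
    lo = x.min(axis=0)
    span = x.max(axis=0) - lo
    span = np.where(span == 0, 1.0, span) if np.ndim(span) else (span or 1.0)
    return (x - lo) / span


def smooth_categorical(matrix: np.ndarray, states: list) -> np.ndarray:
    """Map ordinal states to equally spaced soft targets in [0,1].

    With states (s_0 < ... < s_{K-1}) state s_j maps to j/(K-1); a binary
    state list is the identity. The result feeds a Bernoulli cross-entropy
    as label-smoothed targets.
    """
    m = np.asarray(matrix)
    states = list(states)
    positions = {s: (j / (len(states) - 1) if len(states) > 1 else 0.0)
                 for j, s in enumerate(states)}
    unknown = set(np.unique(m)) - set(states)
    if unknown:
        raise ValueError(f"entries outside the state list: {sorted(unknown)}")
    out = np.empty(m.shape, dtype=float)
    for s, pos in positions.items():
        out[m == s] = pos
    return out


def unsmooth_categorical(matrix: np.ndarray, states: list) -> np.ndarray:
    """Inverse of :func:`smooth_categorical` by nearest state position."""
    states = list(states)
    grid = np.linspace(0.0, 1.0, len(states)) if len(states) > 1 else np.zeros(1)
    idx = np.abs(np.asarray(matrix, dtype=float)[..., None] - grid).argmin(axis=-1)
    return np.asarray(states)[idx]


def discretize_and_onehot(column: np.ndarray, n_bins: int = 5) -> np.ndarray:
    """Quantile-bin a numeric vector and one-hot encode the bins.

    Each output row has exactly one 1. If the column has fewer distinct
    values than bins the bins collapse to the distinct values (with a
    warning); a constant column yields a single all-ones column.
    """
    x = np.asarray(column, dtype=float)
    if x.size == 0:
        raise ValueError("cannot discretize an empty column")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in column")
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    n_distinct = len(np.unique(x))
    if n_distinct < n_bins:
        warnings.warn(f"only {n_distinct} distinct values; collapsing to "
                      f"{n_distinct} bins", stacklevel=2)
        codes = pd.Categorical(x).codes
    else:
        codes = pd.qcut(x, q=n_bins, labels=False, duplicates="drop")
        codes = np.asarray(codes, dtype=int)
    n_cols = int(codes.max()) + 1
    out = np.zeros((x.size, n_cols))
    out[np.arange(x.size), codes] = 1.0
    return out


def preprocess_clinical(table: pd.DataFrame, n_bins: int = 5) -> np.ndarray:
    """One-hot encode a mixed numeric/categorical clinical table.

    Numeric columns are quantile-discretized first; categorical columns are
    one-hot encoded directly.
    """
    blocks = []
    for col in table.columns:
        s = table[col]
        if pd.api.types.is_numeric_dtype(s) and s.nunique() > 2:
            blocks.append(discretize_and_onehot(s.to_numpy(), n_bins))
        else:
            blocks.append(pd.get_dummies(s).to_numpy(dtype=float))
    return np.concatenate(blocks, axis=1)


def assemble_dataset(tables: dict[str, pd.DataFrame],
                     specs: list[ModalitySpec],
                     labels: pd.DataFrame,
                     categorical_states: dict[str, list] | None = None,
                     ) -> MultiOmicDataset:
    """Align per-modality tables and a label table into one dataset.

    Tables are inner-joined on their index (the sample-ID column) and rows
    are put in lexicographic sample-ID order. Continuous modalities are
    min-max scaled per feature; categorical modalities are mapped to soft
    targets over their ordered state list.
    """
    categorical_states = categorical_states or {}
    ids: set | None = None
    for name, t in list(tables.items()) + [("labels", labels)]:
        if t.index.duplicated().any():
            raise ValueError(f"duplicate sample IDs in table {name!r}")
        ids = set(t.index) if ids is None else ids & set(t.index)
    if not ids:
        raise ValueError("no common sample IDs across tables")
    order = sorted(ids, key=str)

    matrices = {}
    for spec in specs:
        t = tables[spec.name].loc[order]
        if spec.kind == "continuous":
            matrices[spec.name] = scale_minmax(t.to_numpy(dtype=float))
        else:
            states = categorical_states.get(
                spec.name, sorted(np.unique(t.to_numpy()).tolist()))
            matrices[spec.name] = smooth_categorical(t.to_numpy(), states)

    lab = labels.loc[order]
    label_vecs = {c: pd.Categorical(lab[c]).codes.astype(int)
                  for c in lab.columns}
    return MultiOmicDataset(sample_ids=[str(i) for i in order], specs=specs,
                            matrices=matrices, labels=label_vecs)


def make_stratified_folds(labels: np.ndarray, n_folds: int = 5,
                          seed: int = DEFAULT_FOLD_SEED,
                          task: str = "task") -> FoldAssignment:
    """Stratified k-fold assignment, a pure function of (labels, n_folds, seed).

    Per-fold class counts differ from proportional allocation by at most one
    sample per class. The same assignment is reused for every experiment on
    a task so that all methods see identical splits.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    too_small = classes[counts < n_folds]
    if too_small.size:
        raise ValueError(f"class {too_small[0]!r} has fewer than "
                         f"{n_folds} members")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_of = np.empty(len(y), dtype=int)
    for k, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        fold_of[test_idx] = k
    return FoldAssignment(task=task, n_folds=n_folds, fold_of=fold_of, seed=seed)
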