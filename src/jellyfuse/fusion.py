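"""Multi-view feature fusion strategies.

A *multi-view dataset* holds one feature block per extractor (e.g. three
CNN backbones emitting 512-, 1024- and 1024-wide descriptors per image).
Four fusion strategies build a single design matrix from the blocks:

* **CFS** — plain concatenation of all blocks;
* **AWFS** — concatenation with one adaptive scalar weight per block,
  set from each block's standalone validation accuracy;
* **MOWFS** — the per-block weights are decision variables of a
  metaheuristic minimizing a classifier's validation mean-squared error;
* **FOWFS** — one weight per feature column, optimized the same way.

After optimization, entries with weight above 0.5 form the *highest-ranked*
feature set: whole blocks for MOWFS, individual columns for FOWFS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score
from sklearn.model_selection import StratifiedShuffleSplit, train_test_split

from .classifiers import ClassifierSpec, make_classifier
from .optim import OPTIMIZERS, AJSConfig, OptimizationResult, SearchSpace

__all__ = [
    "FeatureBlock",
    "MultiViewDataset",
    "WeightScheme",
    "SelectionMask",
    "FusedFeatureSet",
    "DegenerateSelectionError",
    "StratificationError",
    "SplitSpec",
    "concat_blocks",
    "apply_model_weights",
    "apply_feature_weights",
    "select_ranked",
    "expand_block_mask",
    "mse_cost",
    "awfs",
    "mowfs",
    "fowfs",
]


class DegenerateSelectionError(ValueError):
    """No entry survived the weight threshold: the ranked set is empty."""


class StratificationError(ValueError):
    """A data split would leave a fold without at least two classes."""


@dataclass
class FeatureBlock:
    """One extractor's ``n_samples x d`` feature matrix."""

    extractor_id: str
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] < 1 or m.shape[1] < 1:
            raise ValueError("feature block must be a non-empty 2-D matrix")
        if not np.all(np.isfinite(m)):
            raise ValueError(f"block {self.extractor_id!r} contains non-finite values")
        self.matrix = m

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def d(self) -> int:
        return self.matrix.shape[1]


@dataclass
class MultiViewDataset:
    """An ordered set of feature blocks over the same samples, plus labels."""

    blocks: list
    labels: np.ndarray
    n_classes: int | None = None

    def __post_init__(self):
        if not self.blocks:
            raise ValueError("dataset needs at least one feature block")
        n = self.blocks[0].n_samples
        if any(b.n_samples != n for b in self.blocks):
            raise ValueError("all blocks must cover the same samples")
        labels = np.asarray(self.labels, dtype=int)
        if labels.shape != (n,):
            raise ValueError("labels must have one entry per sample")
        present = np.unique(labels)
        if self.n_classes is None:
            self.n_classes = int(present.max()) + 1
        if labels.min() < 0 or labels.max() >= self.n_classes:
            raise ValueError("labels must take values in 0..n_classes-1")
        if present.size < 2:
            raise ValueError("at least two classes must be present")
        self.labels = labels

    @property
    def n_samples(self) -> int:
        return self.blocks[0].n_samples

    @property
    def block_dims(self) -> tuple:
        return tuple(b.d for b in self.blocks)

    @property
    def total_dim(self) -> int:
        return sum(self.block_dims)


@dataclass
class WeightScheme:
    """A fusion weight vector: one entry per block (``level='model'``) or
    one per fused column (``level='feature'``), each within [0, 1]."""

    level: str
    weights: np.ndarray

    def __post_init__(self):
        if self.level not in ("model", "feature"):
            raise ValueError("level must be 'model' or 'feature'")
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1:
            raise ValueError("weights must be a 1-D vector")
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("weights must lie within [0, 1]")
        self.weights = w


@dataclass
class SelectionMask:
    """Boolean keep-flags aligned with the fused column order."""

    keep: np.ndarray

    def __post_init__(self):
        self.keep = np.asarray(self.keep, dtype=bool)

    @property
    def n_selected(self) -> int:
        return int(self.keep.sum())


@dataclass
class FusedFeatureSet:
    """A fused design matrix with provenance back to extractor columns."""

    matrix: np.ndarray
    strategy: str
    weights_used: WeightScheme | None = None
    mask: SelectionMask | None = None
    column_provenance: pd.DataFrame | None = None

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


def _provenance(dataset: MultiViewDataset) -> pd.DataFrame:
    rows = [
        (b.extractor_id, j)
        for b in dataset.blocks
        for j in range(b.d)
    ]
    return pd.DataFrame(rows, columns=["extractor_id", "column"])


def concat_blocks(dataset: MultiViewDataset) -> FusedFeatureSet:
    """Plain concatenation of all blocks in order (the CFS strategy)."""
    matrix = np.hstack([b.matrix for b in dataset.blocks])
    return FusedFeatureSet(matrix, "CFS", column_provenance=_provenance(dataset))


def apply_model_weights(dataset: MultiViewDataset, w: WeightScheme) -> FusedFeatureSet:
    """Scale each block by its scalar weight, then concatenate."""
    if w.level != "model":
        raise ValueError("apply_model_weights needs a model-level weight scheme")
    if len(w.weights) != len(dataset.blocks):
        raise ValueError("one weight per block is required")
    matrix = np.hstack(
        [wi * b.matrix for wi, b in zip(w.weights, dataset.blocks)]
    )
    return FusedFeatureSet(matrix, "AWFS", weights_used=w,
                           column_provenance=_provenance(dataset))


def apply_feature_weights(dataset: MultiViewDataset, w: WeightScheme) -> FusedFeatureSet:
    """Multiply every fused column by its own weight."""
    if w.level != "feature":
        raise ValueError("apply_feature_weights needs a feature-level weight scheme")
    if len(w.weights) != dataset.total_dim:
        raise ValueError(
            f"expected {dataset.total_dim} weights, got {len(w.weights)}"
        )
    matrix = np.hstack([b.matrix for b in dataset.blocks]) * w.weights
    return FusedFeatureSet(matrix, "FOWFS", weights_used=w,
                           column_provenance=_provenance(dataset))


def select_ranked(w: WeightScheme, threshold: float = 0.5) -> SelectionMask:
    """Keep the entries whose weight strictly exceeds *threshold*.

    The rule is strict: a weight of exactly 0.5 is dropped.  An empty
    selection raises :class:`DegenerateSelectionError` (callers that prefer
    a fallback catch it).
    """
    keep = w.weights > threshold
    if not keep.any():
        raise DegenerateSelectionError(
            f"no weight exceeds {threshold}; the ranked feature set is empty"
        )
    return SelectionMask(keep)


def expand_block_mask(keep_blocks: np.ndarray, block_dims: Sequence[int]) -> np.ndarray:
    """Expand per-block keep flags to the fused column order."""
    return np.repeat(np.asarray(keep_blocks, dtype=bool), np.asarray(block_dims))


# ---------------------------------------------------------------------------
# Wrapper cost and the adaptive / optimized strategies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """Split fractions: ``test_frac`` for the outer train/test partition and
    ``val_frac`` for the inner train/validation partitions the wrapper cost
    uses (all stratified).  The cost averages over ``n_splits`` inner
    shuffle-splits; a single small fold is too easy to overfit."""

    test_frac: float = 0.2
    val_frac: float = 0.3
    n_splits: int = 3


def _stratified_split(X, y, frac, seed):
    counts = np.bincount(y)
    if np.any(counts[np.unique(y)] < 2):
        raise StratificationError(
            "every class needs at least 2 samples for a stratified split"
        )
    try:
        return train_test_split(
            X, y, test_size=frac, stratify=y, random_state=seed
        )
    except ValueError as exc:  # pragma: no cover - sklearn message passthrough
        raise StratificationError(str(exc)) from exc


def stratified_indices(labels: np.ndarray, test_frac: float, seed: int):
    """Stratified row-index partition (train, test)."""
    idx = np.arange(len(labels))
    tr, te = _stratified_split(idx, np.asarray(labels, dtype=int), test_frac, seed)[:2]
    return np.sort(tr), np.sort(te)


def _one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(y), n_classes))
    out[np.arange(len(y)), y] = 1.0
    return out


def _inner_splits(y: np.ndarray, split_spec: "SplitSpec", seed: int):
    counts = np.bincount(y)
    if np.any(counts[np.unique(y)] < 2):
        raise StratificationError(
            "every class needs at least 2 samples for a stratified split"
        )
    sss = StratifiedShuffleSplit(
        n_splits=split_spec.n_splits,
        test_size=split_spec.val_frac,
        random_state=seed,
    )
    try:
        yield from sss.split(np.zeros((len(y), 1)), y)
    except ValueError as exc:  # pragma: no cover - sklearn message passthrough
        raise StratificationError(str(exc)) from exc


def _proba_matrix(clf, X, classes_present, n_classes):
    """Class-probability matrix re-indexed onto 0..n_classes-1."""
    p = clf.predict_proba(X)
    full = np.zeros((X.shape[0], n_classes))
    full[:, np.asarray(classes_present, dtype=int)] = p
    return full


def mse_cost(
    w: WeightScheme,
    dataset: MultiViewDataset,
    labels: np.ndarray | None = None,
    classifier_spec: ClassifierSpec | None = None,
    split_spec: SplitSpec | None = None,
    seed: int = 0,
) -> float:
    """Wrapper cost: validation MSE of a classifier on the weighted fusion.

    The weighted fused matrix is partitioned by stratified shuffle-splits
    (``split_spec.val_frac`` held out); per split the classifier is fitted
    on the remainder and the mean squared difference between one-hot true
    labels and predicted class-probability vectors is computed on the
    held-out part.  The cost is the average over ``split_spec.n_splits``
    splits and is deterministic for a fixed ``(w, seed)``.
    """
    classifier_spec = classifier_spec or ClassifierSpec("svm", seed=seed)
    split_spec = split_spec or SplitSpec()
    y = dataset.labels if labels is None else np.asarray(labels, dtype=int)
    fused = (
        apply_model_weights(dataset, w)
        if w.level == "model"
        else apply_feature_weights(dataset, w)
    )
    X = fused.matrix
    target_all = _one_hot(y, dataset.n_classes)
    costs = []
    for tr, val in _inner_splits(y, split_spec, seed):
        clf = make_classifier(classifier_spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # MLP convergence chatter
            clf.fit(X[tr], y[tr])
        proba = _proba_matrix(clf, X[val], clf.classes_, dataset.n_classes)
        costs.append(float(np.mean((proba - target_all[val]) ** 2)))
    return float(np.mean(costs))


def awfs(
    dataset: MultiViewDataset,
    labels: np.ndarray | None = None,
    classifier_spec: ClassifierSpec | None = None,
    seed: int = 0,
    split_spec: SplitSpec | None = None,
):
    """Adaptive weighted fusion: each block's weight is its standalone
    validation accuracy rescaled by the best block's accuracy.

    The weights therefore lie in (0, 1] with the strongest block at 1, and
    identical blocks receive identical weights.  Returns the model-level
    weight scheme and the weighted fused set.
    """
    classifier_spec = classifier_spec or ClassifierSpec("svm", seed=seed)
    split_spec = split_spec or SplitSpec()
    y = dataset.labels if labels is None else np.asarray(labels, dtype=int)
    accs = []
    for block in dataset.blocks:
        fold_accs = []
        for tr, val in _inner_splits(y, split_spec, seed):
            clf = make_classifier(classifier_spec)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(block.matrix[tr], y[tr])
            fold_accs.append(accuracy_score(y[val], clf.predict(block.matrix[val])))
        accs.append(np.mean(fold_accs))
    accs = np.asarray(accs, dtype=float)
    top = accs.max()
    weights = np.ones_like(accs) if top == 0 else accs / top
    scheme = WeightScheme("model", weights)
    fused = apply_model_weights(dataset, scheme)
    fused.strategy = "AWFS"
    return scheme, fused


class OptimizedFusion(NamedTuple):
    """Outcome of MOWFS/FOWFS: the optimized weights, the column keep-mask,
    the reduced fused set and the optimizer run record."""

    weights: WeightScheme
    mask: SelectionMask
    fused: FusedFeatureSet
    optimization: OptimizationResult


def _optimized_weights(
    dataset, level, classifier_spec, optimizer, optimizer_config, cost_seed, split_spec
):
    dim = len(dataset.blocks) if level == "model" else dataset.total_dim
    space = SearchSpace.unit(dim)

    def objective(x):
        return mse_cost(
            WeightScheme(level, np.clip(x, 0.0, 1.0)),
            dataset,
            classifier_spec=classifier_spec,
            split_spec=split_spec,
            seed=cost_seed,
        )

    run = OPTIMIZERS[optimizer](objective, space, optimizer_config)
    return WeightScheme(level, np.clip(run.best_position, 0.0, 1.0)), run


def mowfs(
    dataset: MultiViewDataset,
    labels: np.ndarray | None = None,
    classifier_spec: ClassifierSpec | None = None,
    optimizer_config=None,
    optimizer: str = "ajs",
    threshold: float = 0.5,
    split_spec: SplitSpec | None = None,
    on_degenerate: str = "raise",
) -> OptimizedFusion:
    """Model-level optimized weighted fusion.

    The per-block weights are the decision variables (dimension = number of
    blocks, bounds [0, 1]); the metaheuristic minimizes the classifier's
    validation MSE.  Blocks whose optimized weight exceeds *threshold* form
    the ranked set; the returned fused matrix is the weighted concatenation
    restricted to those blocks.

    Because the wrapper cost depends mostly on weight *ratios* (many
    classifiers are insensitive to a common rescaling), the optimum can
    leave every weight below the threshold.  ``on_degenerate='raise'``
    (default) raises :class:`DegenerateSelectionError` in that case;
    ``'full'`` keeps the full weighted set with a warning.
    """
    if labels is not None:
        dataset = MultiViewDataset(dataset.blocks, labels, dataset.n_classes)
    optimizer_config = optimizer_config or AJSConfig()
    w, run = _optimized_weights(
        dataset, "model", classifier_spec, optimizer, optimizer_config,
        optimizer_config.seed, split_spec,
    )
    keep_blocks = w.weights > threshold
    if not keep_blocks.any():
        if on_degenerate != "full":
            raise DegenerateSelectionError(
                f"no block weight exceeds {threshold}; the ranked set is empty"
            )
        warnings.warn("empty ranked set; keeping the full weighted fusion")
        keep_blocks = np.ones(len(dataset.blocks), dtype=bool)
    mask = SelectionMask(expand_block_mask(keep_blocks, dataset.block_dims))
    weighted = apply_model_weights(dataset, w)
    fused = FusedFeatureSet(
        weighted.matrix[:, mask.keep],
        "MOWFS",
        weights_used=w,
        mask=mask,
        column_provenance=weighted.column_provenance[mask.keep].reset_index(drop=True),
    )
    return OptimizedFusion(w, mask, fused, run)


def fowfs(
    dataset: MultiViewDataset,
    labels: np.ndarray | None = None,
    classifier_spec: ClassifierSpec | None = None,
    optimizer_config=None,
    optimizer: str = "ajs",
    threshold: float = 0.5,
    split_spec: SplitSpec | None = None,
    on_degenerate: str = "raise",
) -> OptimizedFusion:
    """Feature-level optimized weighted fusion.

    One decision variable per fused column (2560 at the default 512/1024/1024
    block widths).  Columns whose optimized weight exceeds *threshold* are
    retained for final classification.  ``on_degenerate`` behaves as in
    :func:`mowfs`.
    """
    if labels is not None:
        dataset = MultiViewDataset(dataset.blocks, labels, dataset.n_classes)
    optimizer_config = optimizer_config or AJSConfig()
    w, run = _optimized_weights(
        dataset, "feature", classifier_spec, optimizer, optimizer_config,
        optimizer_config.seed, split_spec,
    )
    try:
        mask = select_ranked(w, threshold)
    except DegenerateSelectionError:
        if on_degenerate != "full":
            raise
        warnings.warn("empty ranked set; keeping the full weighted fusion")
        mask = SelectionMask(np.ones(dataset.total_dim, dtype=bool))
    weighted = apply_feature_weights(dataset, w)
    fused = FusedFeatureSet(
        weighted.matrix[:, mask.keep],
        "FOWFS",
        weights_used=w,
        mask=mask,
        column_provenance=weighted.column_provenance[mask.keep].reset_index(drop=True),
    )
    return OptimizedFusion(w, mask, fused, run)
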