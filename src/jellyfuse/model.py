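"""Model/Results surface over the fusion strategies.

:class:`FeatureFusionModel` is constructed from a multi-view dataset (or a
feature-table DataFrame) together with the wrapper classifier; ``fit``
selects a fusion strategy and, for the optimized strategies, a metaheuristic,
and returns a :class:`FusionResults` carrying the estimated weights, the
ranked-set mask, the optimizer's convergence diagnostics and an ``evaluate``
/ ``summary`` pair for held-out performance.

The model draws one stratified train/test partition up front; weights are
estimated on the training rows only, so the held-out fold never leaks into
the wrapper cost.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classifiers import ClassifierSpec
from .evaluation import MetricsReport, train_eval
from .fusion import (
    FeatureBlock,
    FusedFeatureSet,
    MultiViewDataset,
    SelectionMask,
    SplitSpec,
    WeightScheme,
    apply_feature_weights,
    apply_model_weights,
    awfs,
    concat_blocks,
    fowfs,
    mowfs,
    stratified_indices,
)
from .io import frame_to_dataset
from .optim import make_optimizer_config

__all__ = ["FeatureFusionModel", "FusionResults"]

STRATEGIES = ("cfs", "awfs", "mowfs", "fowfs")


class FeatureFusionModel:
    """Weighted fusion of multi-extractor feature blocks.

    Parameters
    ----------
    dataset : MultiViewDataset
        Feature blocks plus class labels.
    classifier : str or ClassifierSpec
        The wrapper classifier whose validation MSE drives the optimized
        strategies and which scores the final fused set.
    split_spec : SplitSpec, optional
        Outer test and inner validation fractions.
    split_seed : int
        Seed of the outer stratified train/test partition, drawn once at
        construction.
    """

    def __init__(self, dataset: MultiViewDataset, classifier="svm",
                 split_spec: SplitSpec | None = None, split_seed: int = 0):
        self.dataset = dataset
        self.classifier_spec = (
            classifier
            if isinstance(classifier, ClassifierSpec)
            else ClassifierSpec(classifier)
        )
        self.split_spec = split_spec or SplitSpec()
        self.train_idx, self.test_idx = stratified_indices(
            dataset.labels, self.split_spec.test_frac, split_seed
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label", **kwargs):
        """Build from a feature table with ``block:<id>:<index>`` columns."""
        return cls(frame_to_dataset(df, label_col=label_col), **kwargs)

    def _train_dataset(self) -> MultiViewDataset:
        return MultiViewDataset(
            [FeatureBlock(b.extractor_id, b.matrix[self.train_idx]) for b in self.dataset.blocks],
            self.dataset.labels[self.train_idx],
            n_classes=self.dataset.n_classes,
        )

    def fit(
        self,
        strategy: str = "fowfs",
        optimizer: str = "ajs",
        threshold: float = 0.5,
        seed: int = 0,
        on_degenerate: str = "raise",
        **optimizer_kwargs,
    ) -> "FusionResults":
        """Estimate fusion weights on the training rows.

        ``cfs`` needs no fitting; ``awfs`` measures standalone block
        accuracies; ``mowfs``/``fowfs`` run the named metaheuristic
        (``ajs``, ``ga`` or ``pso``) over the weight box [0, 1]^dim.  The
        returned results apply the estimated weights/mask to *all* rows so
        the held-out fold can be scored.
        """
        strategy = strategy.lower()
        if strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
        train_ds = self._train_dataset()
        weights = mask = run = None
        if strategy == "cfs":
            fused = concat_blocks(self.dataset)
        elif strategy == "awfs":
            weights, _ = awfs(
                train_ds, classifier_spec=self.classifier_spec,
                seed=seed, split_spec=self.split_spec,
            )
            fused = apply_model_weights(self.dataset, weights)
        else:
            config = make_optimizer_config(optimizer, seed=seed, **optimizer_kwargs)
            func = mowfs if strategy == "mowfs" else fowfs
            weights, mask, _, run = func(
                train_ds,
                classifier_spec=self.classifier_spec,
                optimizer_config=config,
                optimizer=optimizer,
                threshold=threshold,
                split_spec=self.split_spec,
                on_degenerate=on_degenerate,
            )
            apply = apply_model_weights if strategy == "mowfs" else apply_feature_weights
            weighted = apply(self.dataset, weights)
            fused = FusedFeatureSet(
                weighted.matrix[:, mask.keep],
                strategy.upper(),
                weights_used=weights,
                mask=mask,
                column_provenance=weighted.column_provenance[mask.keep].reset_index(drop=True),
            )
        return FusionResults(
            self, strategy,
            optimizer if strategy in ("mowfs", "fowfs") else None,
            fused, weights, mask, run, seed,
        )


class FusionResults:
    """Fitted fusion weights plus diagnostics.

    Attributes
    ----------
    fused : FusedFeatureSet
        The strategy's final design matrix over all samples (ranked subset
        for MOWFS/FOWFS).
    weights : WeightScheme or None
        Estimated block- or feature-level weights.
    mask : SelectionMask or None
        Ranked-set keep flags over the fused column order.
    optimization : OptimizationResult or None
        Best cost, evaluation count and the best-so-far trace.
    """

    def __init__(self, model, strategy, optimizer, fused, weights, mask, optimization, seed):
        self.model = model
        self.strategy = strategy
        self.optimizer = optimizer
        self.fused = fused
        self.weights = weights
        self.mask = mask
        self.optimization = optimization
        self.seed = seed
        self._metrics: MetricsReport | None = None

    @property
    def n_selected(self) -> int:
        return self.fused.n_features

    def evaluate(self, classifier=None) -> MetricsReport:
        """Score the fused set on the held-out test fold fixed at model
        construction (trained on the training fold)."""
        spec = (
            self.model.classifier_spec
            if classifier is None
            else (classifier if isinstance(classifier, ClassifierSpec) else ClassifierSpec(classifier))
        )
        report = train_eval(
            self.fused,
            self.model.dataset.labels,
            spec=spec,
            split_spec=self.model.split_spec,
            seed=self.seed,
            train_idx=self.model.train_idx,
            test_idx=self.model.test_idx,
        )
        self._metrics = report
        return report

    def weight_frame(self) -> pd.DataFrame:
        """Weights with provenance and keep flags, one row per entry."""
        if self.weights is None:
            raise ValueError("strategy has no weights (CFS)")
        w = self.weights.weights
        ds = self.model.dataset
        if self.weights.level == "model":
            ids = [b.extractor_id for b in ds.blocks]
            if self.mask is not None:
                offsets = np.cumsum((0,) + ds.block_dims[:-1])
                keep = self.mask.keep[offsets]
            else:
                keep = np.ones(len(ids), dtype=bool)
            return pd.DataFrame({"extractor_id": ids, "weight": w, "selected": keep})
        prov = pd.DataFrame(
            [(b.extractor_id, j) for b in ds.blocks for j in range(b.d)],
            columns=["extractor_id", "column"],
        )
        prov["weight"] = w
        prov["selected"] = self.mask.keep if self.mask is not None else True
        return prov

    def summary(self) -> str:
        """Plain-text report of the fit, statsmodels-style."""
        ds = self.model.dataset
        lines = [
            "Feature Fusion Results",
            "=" * 58,
            f"strategy:            {self.strategy.upper()}",
            f"optimizer:           {self.optimizer or '-'}",
            f"wrapper classifier:  {self.model.classifier_spec.kind.upper()}",
            f"samples / classes:   {ds.n_samples} / {ds.n_classes}",
            f"block widths:        {' + '.join(map(str, ds.block_dims))} = {ds.total_dim}",
            f"columns retained:    {self.n_selected}",
        ]
        if self.weights is not None and self.weights.level == "model":
            for b, wi in zip(ds.blocks, self.weights.weights):
                lines.append(f"  weight[{b.extractor_id}] = {wi:.4f}")
        elif self.weights is not None:
            w = self.weights.weights
            lines.append(
                f"  feature weights: mean={w.mean():.4f}  >0.5 count={(w > 0.5).sum()}"
            )
        if self.optimization is not None:
            lines.append(
                f"best cost (val MSE): {self.optimization.best_cost:.6f} "
                f"after {self.optimization.n_evals} evaluations"
            )
        if self._metrics is not None:
            lines.append("-" * 58)
            lines.append(f"held-out test: {self._metrics}")
        return "\n".join(lines)
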