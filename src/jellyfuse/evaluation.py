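"""Classifier evaluation harness, multiclass metrics, Friedman rank test and
the fused-vs-ranked comparison report.

Metrics follow the macro-averaging convention: precision, sensitivity
(recall), F1 and one-vs-rest ROC-AUC are unweighted means over classes.

The package ships the published validation-accuracy and recognition tables
for the two dermoscopy benchmarks (HAM 10000, seven lesion classes; BCN
20000, eight) as CSV fixtures, so the improvement-over-concatenation deltas
and the rank-based comparison can be recomputed without the image data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from math import trunc

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    precision_recall_fscore_support,
    roc_auc_score,
)
from scipy.stats import rankdata

from .classifiers import ClassifierSpec, make_classifier
from .fusion import FusedFeatureSet, SplitSpec, _proba_matrix, _stratified_split

__all__ = [
    "MetricsReport",
    "RankTable",
    "train_eval",
    "auc_ovr",
    "friedman_statistic",
    "rank_methods",
    "delta_report",
    "load_validation_table",
    "load_recognition_table",
]


@dataclass
class MetricsReport:
    """Macro-averaged multiclass performance summary."""

    accuracy: float
    precision: float
    sensitivity: float
    f1: float
    auc: float
    per_class: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "f1": self.f1,
            "auc": self.auc,
            "per_class": self.per_class.to_dict(orient="list"),
        }

    def __str__(self) -> str:
        head = (
            f"accuracy={self.accuracy:.4f}  precision={self.precision:.4f}  "
            f"sensitivity={self.sensitivity:.4f}  f1={self.f1:.4f}  auc={self.auc:.4f}"
        )
        return head


def auc_ovr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Macro one-vs-rest ROC-AUC from an ``n x C`` class-probability matrix.

    Classes absent from *labels* are skipped with a warning rather than
    failing the whole computation.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    aucs = []
    for c in range(scores.shape[1]):
        y = labels == c
        if y.all() or not y.any():
            warnings.warn(
                f"class {c} absent from labels; skipped in macro AUC",
                stacklevel=2,
            )
            continue
        aucs.append(roc_auc_score(y, scores[:, c]))
    if not aucs:
        raise ValueError("no class present in labels; AUC undefined")
    return float(np.mean(aucs))


def train_eval(
    fused: FusedFeatureSet,
    labels: np.ndarray,
    spec: ClassifierSpec | None = None,
    split_spec: SplitSpec | None = None,
    seed: int = 0,
    train_idx: np.ndarray | None = None,
    test_idx: np.ndarray | None = None,
) -> MetricsReport:
    """Fit the classifier on a stratified training fold of the fused matrix
    and score the held-out test fold.

    Pass ``train_idx``/``test_idx`` to reuse a partition fixed elsewhere
    (e.g. one drawn before weight optimization); otherwise a fresh
    stratified split is drawn from *seed*.
    """
    spec = spec or ClassifierSpec("svm", seed=seed)
    split_spec = split_spec or SplitSpec()
    y = np.asarray(labels, dtype=int)
    n_classes = int(y.max()) + 1
    if train_idx is not None and test_idx is not None:
        X_tr, X_te = fused.matrix[train_idx], fused.matrix[test_idx]
        y_tr, y_te = y[train_idx], y[test_idx]
    else:
        X_tr, X_te, y_tr, y_te = _stratified_split(
            fused.matrix, y, split_spec.test_frac, seed
        )
    clf = make_classifier(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X_tr, y_tr)
    y_pred = clf.predict(X_te)
    proba = _proba_matrix(clf, X_te, clf.classes_, n_classes)
    prec, rec, f1, support = precision_recall_fscore_support(
        y_te, y_pred, labels=np.arange(n_classes), zero_division=0
    )
    present = np.isin(np.arange(n_classes), np.unique(y_te))
    per_class = pd.DataFrame(
        {
            "class": np.arange(n_classes),
            "precision": prec,
            "recall": rec,
            "f1": f1,
            "support": support,
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        auc = auc_ovr(proba, y_te)
    return MetricsReport(
        accuracy=float(accuracy_score(y_te, y_pred)),
        precision=float(prec[present].mean()),
        sensitivity=float(rec[present].mean()),
        f1=float(f1[present].mean()),
        auc=auc,
        per_class=per_class,
    )


# ---------------------------------------------------------------------------
# Friedman rank comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankTable:
    """Per-method rank sums over N datasets for k methods.

    Within each dataset the k methods receive ranks 1..k with rank k for the
    best performer (ties averaged), so the rank sums of the strongest
    methods are the largest, and the sums always total N*k*(k+1)/2.
    """

    R: np.ndarray
    N: int
    k: int

    def __post_init__(self):
        R = np.asarray(self.R, dtype=float)
        object.__setattr__(self, "R", R)
        if len(R) != self.k:
            raise ValueError("R must contain one rank sum per method (k entries)")
        expected = self.N * self.k * (self.k + 1) / 2
        if not np.isclose(R.sum(), expected):
            raise ValueError(
                f"rank sums total {R.sum()}, expected N*k*(k+1)/2 = {expected}"
            )


def rank_methods(accuracies: pd.DataFrame) -> RankTable:
    """Rank methods within each dataset and sum the ranks per method.

    *accuracies* is a methods x datasets table; higher accuracy earns a
    higher rank (best method gets rank k), ties receive average ranks.
    """
    if accuracies.isna().any().any():
        raise ValueError("accuracy table must have no missing cells")
    ranks = accuracies.apply(lambda col: rankdata(col.to_numpy()), axis=0)
    R = ranks.sum(axis=1).to_numpy()
    return RankTable(R=R, N=accuracies.shape[1], k=accuracies.shape[0])


def friedman_statistic(table: RankTable, paper_rounding: bool = False) -> float:
    """Friedman chi-square statistic from rank sums:

        FM = 12 / (N k (k+1)) * sum(R^2) - 3 N (k+1)

    With ``paper_rounding`` the leading coefficient is truncated to three
    decimals before multiplying, replicating a common hand-calculation
    shortcut (e.g. 12/144 -> 0.083); default is full precision.
    """
    coef = 12.0 / (table.N * table.k * (table.k + 1))
    if paper_rounding:
        coef = trunc(coef * 1000) / 1000
    return float(coef * np.sum(table.R**2) - 3.0 * table.N * (table.k + 1))


# ---------------------------------------------------------------------------
# Published-table fixtures and the delta report
# ---------------------------------------------------------------------------

def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("jellyfuse.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_validation_table(classifier: str | None = None) -> pd.DataFrame:
    """Published fused-set vs ranked-set validation accuracies per
    classifier, dataset and fusion strategy."""
    df = _read_packaged("validation_accuracy.csv")
    if classifier is not None:
        df = df[df["classifier"] == classifier.lower()].reset_index(drop=True)
        if df.empty:
            raise ValueError(f"unknown classifier {classifier!r}")
    return df

def load_recognition_table(dataset: str | None = None) -> pd.DataFrame:
    """Published recognition metrics (accuracy/precision/sensitivity/F1) for
    the individual backbones and all fusion strategies, in tidy form."""
    df = _read_packaged("recognition.csv")
    if dataset is not None:
        df = df[df["dataset"] == dataset].reset_index(drop=True)
        if df.empty:
            raise ValueError(f"unknown dataset {dataset!r}")
    return df


def parse_dim(dim: str | int) -> int:
    """Total width of a dimensionality cell such as ``512+1024``."""
    return int(sum(int(part) for part in str(dim).split("+")))


def delta_report(results: pd.DataFrame | None = None) -> pd.DataFrame:
    """Improvement of every fusion strategy over plain concatenation (CFS),
    in percentage points, for both the fused and the ranked feature sets.

    *results* defaults to the packaged validation-accuracy table; any table
    with the same columns works.  Deltas are computed strictly from the
    table cells (accuracy_strategy − accuracy_CFS, scaled to percentage
    points and rounded to 2 decimals); a missing CFS row is an error.
    """
    df = load_validation_table() if results is None else results.copy()
    required = {"classifier", "dataset", "strategy", "acc_fused", "acc_ranked"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"results table lacks columns: {sorted(missing)}")
    rows = []
    for (clf, ds), grp in df.groupby(["classifier", "dataset"], sort=False):
        cfs = grp[grp["strategy"] == "CFS"]
        if cfs.empty:
            raise ValueError(f"missing CFS baseline row for {clf}/{ds}")
        base_fused = float(cfs["acc_fused"].iloc[0])
        base_ranked = float(cfs["acc_ranked"].iloc[0])
        for _, r in grp.iterrows():
            rows.append(
                {
                    "classifier": clf,
                    "dataset": ds,
                    "strategy": r["strategy"],
                    "acc_fused": float(r["acc_fused"]),
                    "acc_ranked": float(r["acc_ranked"]),
                    "dim_fused": parse_dim(r.get("dim_fused", 0)),
                    "dim_ranked": parse_dim(r.get("dim_ranked", 0)),
                    "delta_fused_pp": round((float(r["acc_fused"]) - base_fused) * 100, 2),
                    "delta_ranked_pp": round((float(r["acc_ranked"]) - base_ranked) * 100, 2),
                }
            )
    return pd.DataFrame(rows)
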