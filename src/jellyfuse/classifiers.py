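"""Classifier specifications shared by the fusion cost and the evaluation
harness.

Four families are supported — decision tree (DT), Gaussian naive Bayes (NB),
multi-layer perceptron (MLP) and support-vector machine (SVM) — all through
their scikit-learn implementations with library-default hyperparameters
unless overridden.  The SVM is configured with ``probability=True`` because
both the fusion cost and the ROC-AUC metric need class-probability
estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = ["ClassifierSpec", "make_classifier", "CLASSIFIER_KINDS"]

CLASSIFIER_KINDS = ("dt", "nb", "mlp", "svm")


@dataclass(frozen=True)
class ClassifierSpec:
    """A named classifier family plus hyperparameter overrides and a seed."""

    kind: str = "svm"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        kind = self.kind.lower()
        if kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}; expected one of {CLASSIFIER_KINDS}")
        object.__setattr__(self, "kind", kind)


def make_classifier(spec: ClassifierSpec):
    """Instantiate a fresh (unfitted) scikit-learn estimator for *spec*.

    Every estimator exposes ``predict_proba``; randomized ones are seeded
    from the spec so repeated builds behave identically.
    """
    hp = dict(spec.hyperparameters)
    if spec.kind == "dt":
        return DecisionTreeClassifier(random_state=spec.seed, **hp)
    if spec.kind == "nb":
        return GaussianNB(**hp)
    if spec.kind == "mlp":
        return MLPClassifier(random_state=spec.seed, **hp)
    # svm: probability estimates required downstream
    hp.setdefault("probability", True)
    return SVC(random_state=spec.seed, **hp)
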