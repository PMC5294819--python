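"""The five classifier kinds, their default hyperparameters, and grid search.

Defaults follow the study replica this package implements: RBF support
vector machine with C = 10 and gamma = 1 (features z-normalised to zero
mean / unit variance on the training rows), Gaussian naive Bayes,
L1-regularised logistic regression with strength lambda = 0.01, k-nearest
neighbours with k = 5, and a decision tree with a minimum of 10 samples to
split a node.  Multiclass handling for the margin-based models is
one-vs-rest.  Hyperparameter grids: powers of ten 1e-5..1e5 for C, gamma
and lambda; an integer 1-30 scan for k and the tree split threshold.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import joblib
import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureDataset, feature_names

CLASSIFIER_KINDS = ("svm", "naive_bayes", "logistic_regression", "knn", "decision_tree")

#: kinds whose inputs are z-normalised with training-fold statistics
NORMALIZED_KINDS = ("svm", "logistic_regression")

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier kind plus hyperparameters; only fields relevant to the
    kind are consulted."""

    kind: str
    C: float = 10.0
    gamma: float = 1.0
    k_neighbors: int = 5
    l1_lambda: float = 0.01
    min_split: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.C <= 0 or self.gamma <= 0 or self.l1_lambda <= 0:
            raise ValueError("C, gamma and l1_lambda must be positive")
        if self.k_neighbors < 1 or self.min_split < 1:
            raise ValueError("k_neighbors and min_split must be positive integers")


def _make_estimator(spec: ClassifierSpec):
    if spec.kind == "svm":
        return OneVsRestClassifier(SVC(C=spec.C, gamma=spec.gamma, kernel="rbf"))
    if spec.kind == "naive_bayes":
        return GaussianNB(var_smoothing=1e-9)
    if spec.kind == "logistic_regression":
        # sklearn's C is the inverse regularization strength; l1_ratio=1
        # selects the pure lasso penalty
        return OneVsRestClassifier(
            LogisticRegression(
                l1_ratio=1.0,
                C=1.0 / spec.l1_lambda,
                solver="liblinear",
                random_state=spec.seed,
                max_iter=1000,
            )
        )
    if spec.kind == "knn":
        return KNeighborsClassifier(n_neighbors=spec.k_neighbors)
    if spec.kind == "decision_tree":
        # sklearn requires min_samples_split >= 2; a scan value of 1 is
        # behaviourally identical to 2
        return DecisionTreeClassifier(
            min_samples_split=max(2, spec.min_split), random_state=spec.seed
        )
    raise AssertionError(spec.kind)


def registry_hash(names: Sequence[str] = ()) -> str:
    names = tuple(names) or feature_names()
    return hashlib.sha256("\n".join(names).encode()).hexdigest()[:16]


@dataclass
class TrainedModel:
    """A fitted classifier plus the training-time normalisation statistics.

    ``norm_mean``/``norm_sd`` are per-feature statistics learned from the
    training rows only (``None`` for kinds trained on raw features);
    zero-SD features use SD 1 so scaling is always defined.
    """

    spec: ClassifierSpec
    estimator: object
    classes: tuple[str, ...]
    norm_mean: np.ndarray | None
    norm_sd: np.ndarray | None
    registry: str = field(default_factory=registry_hash)

    def _transform(self, matrix: np.ndarray) -> np.ndarray:
        if self.norm_mean is None:
            return matrix
        return (matrix - self.norm_mean) / self.norm_sd


def train(
    spec: ClassifierSpec,
    data: FeatureDataset,
    normalize: bool | None = None,
) -> TrainedModel:
    """Fit a classifier; deterministic given ``spec.seed``.

    ``normalize`` overrides the per-kind default (z-normalisation for svm
    and logistic_regression, raw features otherwise).
    """
    labels = np.asarray(data.labels)
    if np.unique(labels).size < 2:
        raise ValueError("training set must contain at least 2 classes")
    if normalize is None:
        normalize = spec.kind in NORMALIZED_KINDS
    if normalize:
        mean = data.matrix.mean(axis=0)
        sd = data.matrix.std(axis=0)
        sd = np.where(sd == 0.0, 1.0, sd)
    else:
        mean = sd = None
    model = TrainedModel(
        spec=spec,
        estimator=_make_estimator(spec),
        classes=tuple(sorted(np.unique(labels).tolist())),
        norm_mean=mean,
        norm_sd=sd,
    )
    model.estimator.fit(model._transform(data.matrix), labels)
    return model


def predict(model: TrainedModel, rows: FeatureDataset) -> list[str]:
    """Predict one label (from the training vocabulary) per row."""
    if registry_hash(rows.feature_names) != model.registry:
        raise ValueError("feature registry mismatch between model and rows")
    if len(rows) == 0:
        return []
    return [str(p) for p in model.estimator.predict(model._transform(rows.matrix))]


def stratified_fold_indices(
    labels: Sequence[str], n_folds: int, seed: int
) -> np.ndarray:
    """Deterministic stratified fold assignment (0..n_folds-1 per row).

    Within each class, rows are shuffled with the seeded generator and
    dealt round-robin, so fold class proportions match the pooled data as
    closely as counts allow.
    """
    labels = np.asarray(labels)
    counts = {c: int((labels == c).sum()) for c in np.unique(labels)}
    rare = [c for c, n in counts.items() if n < n_folds]
    if rare:
        raise ValueError(
            f"classes {rare} have fewer rows than the {n_folds} requested folds"
        )
    rng = np.random.default_rng(seed)
    assignment = np.empty(labels.size, dtype=int)
    for c in sorted(counts):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        assignment[idx] = np.arange(idx.size) % n_folds
    return assignment


def _cv_accuracy(
    spec: ClassifierSpec, data: FeatureDataset, folds: np.ndarray, n_folds: int
) -> float:
    correct = 0
    for f in range(n_folds):
        test = np.flatnonzero(folds == f)
        tr = np.flatnonzero(folds != f)
        model = train(spec, data.subset(tr))
        pred = predict(model, data.subset(test))
        correct += sum(p == data.labels[i] for p, i in zip(pred, test))
    return correct / len(data)


def grid_search(
    kind: str,
    data: FeatureDataset,
    folds: int = 10,
    seed: int = 0,
) -> ClassifierSpec:
    """Scan the kind's hyperparameter grid, maximising mean k-fold CV
    accuracy; ties break toward the smaller parameter value.

    svm scans (C, gamma) over powers of ten 1e-5..1e5; logistic_regression
    scans lambda over the same powers; knn and decision_tree scan the
    integers 1-30.  Fold assignment is fixed across candidates and
    deterministic given ``seed``.
    """
    base = ClassifierSpec(kind=kind, seed=seed)
    fold_assignment = stratified_fold_indices(data.labels, folds, seed)

    powers = [10.0**e for e in range(-5, 6)]
    if kind == "svm":
        candidates = [replace(base, C=c, gamma=g) for c, g in itertools.product(powers, powers)]
    elif kind == "logistic_regression":
        candidates = [replace(base, l1_lambda=lam) for lam in powers]
    elif kind == "knn":
        candidates = [replace(base, k_neighbors=k) for k in range(1, 31)]
    elif kind == "decision_tree":
        candidates = [replace(base, min_split=m) for m in range(1, 31)]
    else:  # naive_bayes has no hyperparameters
        candidates = [base]

    best_spec, best_acc = None, -1.0
    for cand in candidates:  # ascending order => strict improvement keeps ties small
        acc = _cv_accuracy(cand, data, fold_assignment, folds)
        if acc > best_acc + 1e-12:
            best_spec, best_acc = cand, acc
    return best_spec


def save_model(model: TrainedModel, path: str) -> None:
    """Persist a trained model with its spec, normalisation stats and
    feature-registry hash."""
    joblib.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "spec": model.spec,
            "estimator": model.estimator,
            "classes": model.classes,
            "norm_mean": model.norm_mean,
            "norm_sd": model.norm_sd,
            "registry": model.registry,
        },
        path,
    )


def load_model(path: str) -> TrainedModel:
    doc = joblib.load(path)
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format {doc.get('format_version')!r}")
    return TrainedModel(
        spec=doc["spec"],
        estimator=doc["estimator"],
        classes=doc["classes"],
        norm_mean=doc["norm_mean"],
        norm_sd=doc["norm_sd"],
        registry=doc["registry"],
    )
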