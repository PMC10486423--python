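"""Hold-out classification harness and metric panel.

The evaluation protocol is a single stratified 70:30 hold-out split per
seed.  Classifiers are instantiated from a small spec mirroring common
default configurations (linear/quadratic/cubic SVM; fine/medium/weighted
KNN; subspace-KNN, AdaBoosted-tree and RUSBoosted-tree ensembles) behind a
uniform fit/predict contract, and every report carries the binary confusion
counts against the declared positive ("malignant") class together with the
derived panel: accuracy, sensitivity, specificity, FNR, FPR and F1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .fusion import FusedFeatures
from .store import LabelVector, SelectionMask

__all__ = [
    "ClassifierSpec",
    "ConfusionCounts",
    "EvaluationReport",
    "CLASSIFIER_PRESETS",
    "make_classifier",
    "holdout_split",
    "counts_from_predictions",
    "metrics_from_counts",
    "evaluate",
    "compare_conditions",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """Family plus per-family parameters, sufficient to instantiate a model."""

    family: str
    parameters: tuple[tuple[str, object], ...] = ()

    def param(self, key: str, default=None):
        return dict(self.parameters).get(key, default)


# Named presets for the benchmark classifier panel.
CLASSIFIER_PRESETS: dict[str, ClassifierSpec] = {
    "linear-svm": ClassifierSpec("linear-svm"),
    "quadratic-svm": ClassifierSpec("quadratic-svm", (("degree", 2),)),
    "cubic-svm": ClassifierSpec("cubic-svm", (("degree", 3),)),
    "fine-knn": ClassifierSpec(
        "knn", (("n_neighbors", 1), ("metric", "euclidean"), ("weights", "equal"))
    ),
    "medium-knn": ClassifierSpec(
        "knn", (("n_neighbors", 10), ("metric", "euclidean"), ("weights", "equal"))
    ),
    "weighted-knn": ClassifierSpec(
        "knn",
        (("n_neighbors", 10), ("metric", "euclidean"), ("weights", "squared-inverse")),
    ),
    "ensemble-subspace-knn": ClassifierSpec(
        "ensemble-subspace-knn", (("n_learners", 30),)
    ),
    "ensemble-boosted-tree": ClassifierSpec(
        "ensemble-boosted-tree", (("n_learners", 30), ("max_splits", 20))
    ),
    "ensemble-rusboost": ClassifierSpec(
        "ensemble-rusboost", (("n_learners", 30), ("max_splits", 20))
    ),
}


def _squared_inverse(dist: np.ndarray) -> np.ndarray:
    """1/d² KNN weights; exact matches (d = 0) take all the weight."""
    with np.errstate(divide="ignore"):
        w = 1.0 / (np.asarray(dist, dtype=float) ** 2)
    inf = np.isinf(w)
    if inf.any():
        rows = inf.any(axis=-1)
        w[rows] = inf[rows].astype(float)
    return w


class RUSBoostClassifier(BaseEstimator, ClassifierMixin):
    """SAMME-style boosting over random-undersampled rounds.

    Each round draws a class-balanced subsample (every class down to the
    minority count, sampling probability proportional to the current boosting
    weights), fits a depth-limited decision tree, and reweights as in
    discrete AdaBoost.  Seeded and deterministic.
    """

    def __init__(self, n_estimators: int = 30, max_splits: int = 20, random_state: int = 0):
        self.n_estimators = n_estimators
        self.max_splits = max_splits
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RUSBoostClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        K = len(self.classes_)
        if K < 2:
            raise ValueError("RUSBoost needs at least two classes")
        rng = np.random.default_rng(self.random_state)
        n = X.shape[0]
        w = np.full(n, 1.0 / n)
        n_min = min(int((y == c).sum()) for c in self.classes_)
        self.estimators_: list[DecisionTreeClassifier] = []
        self.estimator_weights_: list[float] = []
        for m in range(self.n_estimators):
            idx_parts = []
            for c in self.classes_:
                cls_idx = np.flatnonzero(y == c)
                p = w[cls_idx] / w[cls_idx].sum()
                take = min(n_min, cls_idx.size)
                idx_parts.append(rng.choice(cls_idx, size=take, replace=False, p=p))
            idx = np.concatenate(idx_parts)
            tree = DecisionTreeClassifier(
                max_leaf_nodes=self.max_splits + 1, random_state=self.random_state + m
            )
            tree.fit(X[idx], y[idx])
            miss = tree.predict(X) != y
            err = float(w[miss].sum() / w.sum())
            if err <= 0.0:
                self.estimators_.append(tree)
                self.estimator_weights_.append(10.0)  # effectively decisive vote
                break
            if err >= 1.0 - 1.0 / K:
                continue  # no better than chance this round; skip it
            alpha = math.log((1.0 - err) / err) + math.log(K - 1.0)
            w = w * np.exp(alpha * miss)
            w /= w.sum()
            self.estimators_.append(tree)
            self.estimator_weights_.append(alpha)
        if not self.estimators_:  # all rounds chance-level: keep one plain tree
            tree = DecisionTreeClassifier(
                max_leaf_nodes=self.max_splits + 1, random_state=self.random_state
            )
            tree.fit(X, y)
            self.estimators_ = [tree]
            self.estimator_weights_ = [1.0]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        votes = np.zeros((X.shape[0], len(self.classes_)))
        lookup = {c: i for i, c in enumerate(self.classes_)}
        for tree, alpha in zip(self.estimators_, self.estimator_weights_):
            pred = tree.predict(X)
            for i, c in enumerate(pred):
                votes[i, lookup[c]] += alpha
        return self.classes_[np.argmax(votes, axis=1)]


def make_classifier(spec: ClassifierSpec | str, seed: int = 0):
    """Instantiate the estimator behind a classifier spec or preset name."""
    if isinstance(spec, str):
        if spec not in CLASSIFIER_PRESETS:
            raise ValueError(
                f"unknown classifier preset {spec!r}; known: {sorted(CLASSIFIER_PRESETS)}"
            )
        spec = CLASSIFIER_PRESETS[spec]
    family = spec.family
    if family == "linear-svm":
        return SVC(kernel="linear", random_state=seed)
    if family == "quadratic-svm":
        return SVC(kernel="poly", degree=int(spec.param("degree", 2)), random_state=seed)
    if family == "cubic-svm":
        return SVC(kernel="poly", degree=int(spec.param("degree", 3)), random_state=seed)
    if family == "knn":
        k = int(spec.param("n_neighbors", 1))
        if k < 1:
            raise ValueError("neighbor count must be ≥ 1")
        weighting = spec.param("weights", "equal")
        weights = "uniform" if weighting == "equal" else _squared_inverse
        return KNeighborsClassifier(
            n_neighbors=k, metric=spec.param("metric", "euclidean"), weights=weights
        )
    if family == "ensemble-subspace-knn":
        n = int(spec.param("n_learners", 30))
        return BaggingClassifier(
            estimator=KNeighborsClassifier(n_neighbors=1),
            n_estimators=n,
            max_features=0.5,
            bootstrap=False,
            random_state=seed,
        )
    if family == "ensemble-boosted-tree":
        n = int(spec.param("n_learners", 30))
        max_splits = int(spec.param("max_splits", 20))
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_leaf_nodes=max_splits + 1),
            n_estimators=n,
            random_state=seed,
        )
    if family == "ensemble-rusboost":
        return RUSBoostClassifier(
            n_estimators=int(spec.param("n_learners", 30)),
            max_splits=int(spec.param("max_splits", 20)),
            random_state=seed,
        )
    raise ValueError(f"unknown classifier family {family!r}")


def holdout_split(
    labels: LabelVector | np.ndarray | Sequence,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified hold-out split: per-class rounding, ≥ 1 sample on each side.

    Returns sorted (train, test) index arrays that are disjoint and
    exhaustive.  Every class must have at least 2 samples.
    """
    y = labels.as_array() if isinstance(labels, LabelVector) else np.asarray(labels)
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        if idx.size < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        n_train = int(math.floor(train_fraction * idx.size + 0.5))
        n_train = min(max(n_train, 1), idx.size - 1)  # keep ≥ 1 on each side
        perm = rng.permutation(idx)
        train_parts.append(perm[:n_train])
        test_parts.append(perm[n_train:])
    return (
        np.sort(np.concatenate(train_parts)),
        np.sort(np.concatenate(test_parts)),
    )


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts relative to the positive class."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.n_total < 1:
            raise ValueError("confusion counts must cover at least one sample")

    @property
    def n_total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def counts_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, positive_class
) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_t = y_true == positive_class
    pos_p = y_pred == positive_class
    return ConfusionCounts(
        TP=int(np.sum(pos_t & pos_p)),
        FP=int(np.sum(~pos_t & pos_p)),
        TN=int(np.sum(~pos_t & ~pos_p)),
        FN=int(np.sum(pos_t & ~pos_p)),
    )


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN", stacklevel=3)
        return float("nan")
    return num / den


def metrics_from_counts(counts: ConfusionCounts) -> dict[str, float]:
    """The metric panel from binary confusion counts.

    FNR and FPR are the exact complements of sensitivity and specificity.
    Ratios with a zero denominator are NaN with a warning, never 0.
    """
    n = counts.n_total
    sens = _safe_ratio(counts.TP, counts.TP + counts.FN, "sensitivity")
    spec = _safe_ratio(counts.TN, counts.TN + counts.FP, "specificity")
    return {
        "accuracy": (counts.TP + counts.TN) / n,
        "accuracy_pct": 100.0 * (counts.TP + counts.TN) / n,
        "sensitivity": sens,
        "specificity": spec,
        "fnr": 1.0 - sens,
        "fpr": 1.0 - spec,
        "f1": _safe_ratio(
            2.0 * counts.TP, 2.0 * counts.TP + counts.FP + counts.FN, "F1"
        ),
    }


@dataclass(frozen=True)
class EvaluationReport:
    """One classifier × condition × split evaluation."""

    classifier: ClassifierSpec
    condition: str  # "fused-only" or "fused+selected"
    counts: ConfusionCounts
    metrics: dict[str, float]
    split_seed: int
    multiclass_accuracy: float

    def as_dict(self) -> dict:
        return {
            "classifier_family": self.classifier.family,
            "classifier_parameters": dict(self.classifier.parameters),
            "condition": self.condition,
            "counts": {
                "TP": self.counts.TP,
                "FP": self.counts.FP,
                "TN": self.counts.TN,
                "FN": self.counts.FN,
            },
            "metrics": {k: self.metrics[k] for k in sorted(self.metrics)},
            "split_seed": self.split_seed,
            "multiclass_accuracy": self.multiclass_accuracy,
        }


def _resolve_spec(spec: ClassifierSpec | str) -> ClassifierSpec:
    if isinstance(spec, str):
        if spec not in CLASSIFIER_PRESETS:
            raise ValueError(f"unknown classifier preset {spec!r}")
        return CLASSIFIER_PRESETS[spec]
    return spec


def _spec_label(spec: ClassifierSpec) -> str:
    """Distinguishing label for tables (the KNN presets share one family)."""
    for name, preset in CLASSIFIER_PRESETS.items():
        if preset == spec:
            return name
    params = "-".join(f"{k}={v}" for k, v in spec.parameters)
    return f"{spec.family}({params})" if params else spec.family


def _evaluate_split(
    X: np.ndarray,
    labels: LabelVector,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    mask: SelectionMask | None,
    spec: ClassifierSpec,
    seed: int,
    condition: str,
) -> EvaluationReport:
    if mask is not None:
        X = X[:, mask.support]
    y = labels.as_array()
    if len(np.unique(y[train_idx])) < 2:
        raise ValueError("training split contains a single class")
    model = make_classifier(spec, seed=seed)
    model.fit(X[train_idx], y[train_idx])
    y_pred = model.predict(X[test_idx])
    counts = counts_from_predictions(y[test_idx], y_pred, labels.positive_class)
    return EvaluationReport(
        classifier=spec,
        condition=condition,
        counts=counts,
        metrics=metrics_from_counts(counts),
        split_seed=seed,
        multiclass_accuracy=float(np.mean(y_pred == y[test_idx])),
    )


def evaluate(
    fused: FusedFeatures | np.ndarray,
    labels: LabelVector,
    mask: SelectionMask | None = None,
    spec: ClassifierSpec | str = "fine-knn",
    train_fraction: float = 0.7,
    seed: int = 0,
) -> EvaluationReport:
    """Train on the stratified train split, report the panel on the test split.

    A mask, when given, filters columns before training; all fitting uses
    training rows only.
    """
    X = np.asarray(fused.values if isinstance(fused, FusedFeatures) else fused)
    spec = _resolve_spec(spec)
    train_idx, test_idx = holdout_split(labels, train_fraction, seed)
    condition = "fused+selected" if mask is not None else "fused-only"
    return _evaluate_split(X, labels, train_idx, test_idx, mask, spec, seed, condition)


def compare_conditions(
    fused: FusedFeatures | np.ndarray,
    labels: LabelVector,
    selection,
    specs: Sequence[ClassifierSpec | str],
    seeds: Sequence[int],
    train_fraction: float = 0.7,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Accuracy of each classifier with and without the selected subset.

    ``selection`` may be a :class:`SelectionMask`, a ``SelectionResult`` or a
    ``SelectorConfig``; in the last case a label-aware mask is learned per
    seed on the training rows only (no test leakage).  Returns the long-form
    per-run table and a per-classifier/condition mean-accuracy summary laid
    out like the published with/without-selection comparison.
    """
    from .selection import SelectionResult, SelectorConfig, select
    from dataclasses import replace as _dc_replace

    if not specs:
        raise ValueError("need at least one classifier spec")
    X = np.asarray(fused.values if isinstance(fused, FusedFeatures) else fused)
    specs = [_resolve_spec(s) for s in specs]
    rows = []
    for seed in seeds:
        train_idx, test_idx = holdout_split(labels, train_fraction, seed)
        if isinstance(selection, SelectorConfig):
            cfg = _dc_replace(selection, gwo=_dc_replace(selection.gwo, seed=int(seed)))
            sub_labels = LabelVector(
                labels=tuple(np.asarray(labels.labels)[train_idx]),
                classes=labels.classes,
                positive_class=labels.positive_class,
            )
            mask = select(X[train_idx], cfg, labels=sub_labels).mask
        elif isinstance(selection, SelectionResult):
            mask = selection.mask
        else:
            mask = selection
        for spec in specs:
            for condition, m in (("fused-only", None), ("fused+selected", mask)):
                rep = _evaluate_split(
                    X, labels, train_idx, test_idx, m, spec, int(seed), condition
                )
                rows.append(
                    {
                        "classifier": _spec_label(spec),
                        "condition": condition,
                        "seed": int(seed),
                        "accuracy_pct": rep.metrics["accuracy_pct"],
                    }
                )
    table = pd.DataFrame(rows)
    summary = (
        table.pivot_table(
            index="classifier", columns="condition", values="accuracy_pct", aggfunc="mean"
        )
        .reset_index()
        .rename_axis(None, axis=1)
    )
    return table, summary
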