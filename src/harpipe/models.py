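"""Classifiers: bagged random forest plus SVM-RBF and AdaBoost baselines.

The forest is an ensemble of R impurity-reduction decision trees, each fit
on a bootstrap resample of the training rows (drawn with replacement, same
size as the training set) considering sqrt(p) features per split.  The
ensemble prediction averages the per-tree class-indicator votes,
f_hat = (1/R) * sum_r f_r, so the returned probability vector is the vote
share and the predicted class its argmax (ties to the smallest class index).
Tree fitting is delegated to scikit-learn; the vote aggregation is explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix

__all__ = ["ForestModel", "rf_fit", "rf_predict", "baseline_fit_predict"]


@dataclass
class ForestModel:
    """A fitted bagged random forest with its aggregation metadata."""

    n_trees: int
    trees: list
    bootstrap_seeds: list[int]
    class_list: list[str]
    feature_names: list[str]
    _forest: RandomForestClassifier = field(repr=False, default=None)


def _check_classes(labels: np.ndarray) -> list[str]:
    classes = sorted(np.unique(np.asarray(labels).astype(str)).tolist())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    return classes


def rf_fit(
    features: FeatureMatrix,
    labels: np.ndarray | None = None,
    n_trees: int = 100,
    max_depth: int | None = None,
    seed: int = 0,
) -> ForestModel:
    """Fit the bagged forest; per-tree bootstrap seeds derive from ``seed``."""
    y = np.asarray(labels if labels is not None else features.labels).astype(str)
    classes = _check_classes(y)
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_depth=max_depth,
        max_features="sqrt",
        bootstrap=True,
        random_state=int(seed),
    )
    forest.fit(features.values, y)
    return ForestModel(
        n_trees=n_trees,
        trees=list(forest.estimators_),
        bootstrap_seeds=[int(t.random_state) for t in forest.estimators_],
        class_list=[str(c) for c in forest.classes_],
        feature_names=list(features.feature_names),
        _forest=forest,
    )


def rf_predict(model: ForestModel, features: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Vote-share probabilities and argmax class for each row.

    Each tree casts one vote; the probability of class c is the fraction of
    trees voting c.  Ties go to the smallest class index, so a 1/1 split
    between two classes predicts the earlier one in ``class_list``.
    """
    if features.feature_names != model.feature_names:
        raise ValueError("feature names do not match the training matrix")
    x = features.values
    k = len(model.class_list)
    votes = np.zeros((x.shape[0], k))
    for tree in model.trees:
        # trees are trained on encoded labels 0..k-1
        pred = tree.predict(x).astype(int)
        votes[np.arange(x.shape[0]), pred] += 1.0
    prob = votes / len(model.trees)
    pred_idx = prob.argmax(axis=1)  # argmax takes the first (smallest) index on ties
    pred = np.array([model.class_list[i] for i in pred_idx])
    return pred, prob


def baseline_fit_predict(
    kind: str,
    train: FeatureMatrix,
    train_labels: np.ndarray | None,
    test: FeatureMatrix,
    params: dict | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Fit a comparison baseline and predict the test matrix.

    ``kind`` is ``"svm_rbf"`` (RBF kernel, gamma = 1/(p * var), C = 1) or
    ``"adaboost"`` (100 depth-1 trees).  Returns (predictions, class
    probabilities, class list) under the same contract as :func:`rf_predict`.
    """
    if test.feature_names != train.feature_names:
        raise ValueError("feature names do not match the training matrix")
    y = np.asarray(train_labels if train_labels is not None else train.labels).astype(str)
    _check_classes(y)
    params = dict(params or {})
    if kind == "svm_rbf":
        clf = SVC(
            C=params.pop("C", 1.0),
            gamma=params.pop("gamma", "scale"),
            probability=True,
            random_state=int(seed),
            **params,
        )
    elif kind == "adaboost":
        clf = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            n_estimators=params.pop("n_estimators", 100),
            random_state=int(seed),
            **params,
        )
    else:
        raise ValueError(f"unknown baseline kind {kind!r}")
    clf.fit(train.values, y)
    prob = clf.predict_proba(test.values)
    classes = [str(c) for c in clf.classes_]
    pred = np.array([classes[i] for i in prob.argmax(axis=1)])
    return pred, prob, classes
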