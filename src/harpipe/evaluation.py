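"""Leave-one-subject-out evaluation and the metric suite.

LOSO cross-validation holds out every subject in turn, so each fold measures
generalization to a person never seen in training — the regime that matters
for wearable deployments, where inter-subject gain/offset and style
differences dominate.  All train-fold statistics (normalization extremes,
feature ranking, classifier) are computed strictly from training rows.

Metrics are computed from the confusion matrix in closed form: per-class
precision/recall/F1 (zero denominators give 0 with a logged warning),
accuracy, Cohen's kappa (p_o - p_e)/(1 - p_e), the multiclass Matthews
correlation coefficient in covariance form, and one-vs-rest ROC curves from
the classifier's class-probability outputs.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .features import FeatureConfig, FeatureMatrix, build_feature_matrix, minmax_fit_apply
from .models import baseline_fit_predict, rf_fit, rf_predict
from .recordings import Recording, Window, median_denoise, segment
from .selection import rank_features, select_top_k, sgd_fit

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "LosoResult",
    "PipelineConfig",
    "loso_folds",
    "compute_metrics",
    "run_loso",
]


@dataclass
class ConfusionMatrix:
    """K x K count matrix; rows are true classes, columns predicted."""

    class_list: list[str]
    counts: np.ndarray

    @classmethod
    def from_labels(
        cls, y_true: np.ndarray, y_pred: np.ndarray, class_list: list[str] | None = None
    ) -> "ConfusionMatrix":
        y_true = np.asarray(y_true).astype(str)
        y_pred = np.asarray(y_pred).astype(str)
        if class_list is None:
            class_list = sorted(set(y_true) | set(y_pred))
        index = {c: i for i, c in enumerate(class_list)}
        counts = np.zeros((len(class_list), len(class_list)), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[index[t], index[p]] += 1
        return cls(class_list=list(class_list), counts=counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    """Per-class and aggregate scores of one evaluation run."""

    confusion: ConfusionMatrix
    per_class: dict[str, dict[str, float]]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    accuracy: float
    kappa: float
    mcc: float
    roc: dict[str, dict] | None = None

    def to_dict(self) -> dict:
        out = {
            "class_list": self.confusion.class_list,
            "confusion": self.confusion.counts.tolist(),
            "per_class": self.per_class,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "mcc": self.mcc,
        }
        if self.roc is not None:
            out["roc_auc"] = {c: r["auc"] for c, r in self.roc.items()}
        return out


def loso_folds(windows: list[Window]) -> list[tuple[np.ndarray, np.ndarray]]:
    """One (train_indices, test_indices) pair per subject, ordered by id."""
    subjects = np.array([w.subject_id for w in windows])
    uniq = sorted(set(subjects.tolist()))
    if len(uniq) < 2:
        raise ValueError("LOSO needs at least 2 distinct subjects")
    folds = []
    for s in uniq:
        test = np.flatnonzero(subjects == s)
        train = np.flatnonzero(subjects != s)
        folds.append((train, test))
    return folds


def _kappa(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p_o = np.trace(counts) / n
    p_e = float((counts.sum(axis=1) * counts.sum(axis=0)).sum()) / (n * n)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def _mcc(counts: np.ndarray) -> float:
    c = counts.astype(float)
    t = c.sum(axis=1)  # true-class totals
    p = c.sum(axis=0)  # predicted-class totals
    s = c.sum()
    correct = np.trace(c)
    cov_yp = correct * s - float(t @ p)
    cov_pp = s * s - float(p @ p)
    cov_tt = s * s - float(t @ t)
    denom = np.sqrt(cov_pp * cov_tt)
    if denom == 0:
        return 0.0
    return float(cov_yp / denom)


def compute_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    y_prob: np.ndarray | None = None,
    class_list: list[str] | None = None,
) -> MetricsReport:
    """Confusion-matrix metrics plus optional one-vs-rest ROC curves.

    ``y_prob`` columns must follow ``class_list`` order and each row must be
    a probability distribution.
    """
    y_true = np.asarray(y_true).astype(str)
    y_pred = np.asarray(y_pred).astype(str)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    cm = ConfusionMatrix.from_labels(y_true, y_pred, class_list)
    counts = cm.counts
    per_class: dict[str, dict[str, float]] = {}
    for i, c in enumerate(cm.class_list):
        tp = counts[i, i]
        fp = counts[:, i].sum() - tp
        fn = counts[i, :].sum() - tp
        if tp + fp == 0:
            logger.warning("no predictions for class %s; precision set to 0", c)
            precision = 0.0
        else:
            precision = tp / (tp + fp)
        if tp + fn == 0:
            logger.warning("no true instances of class %s; recall set to 0", c)
            recall = 0.0
        else:
            recall = tp / (tp + fn)
        f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
        per_class[c] = {"precision": float(precision), "recall": float(recall), "f1": float(f1)}
    roc = None
    if y_prob is not None:
        y_prob = np.asarray(y_prob, dtype=float)
        if y_prob.shape != (y_true.size, len(cm.class_list)):
            raise ValueError("y_prob must be (rows, classes) in class_list order")
        roc = {}
        for i, c in enumerate(cm.class_list):
            binary = (y_true == c).astype(int)
            if binary.min() == binary.max():
                roc[c] = {"fpr": [], "tpr": [], "auc": float("nan")}
                continue
            fpr, tpr, _ = roc_curve(binary, y_prob[:, i])
            roc[c] = {
                "fpr": fpr.tolist(),
                "tpr": tpr.tolist(),
                "auc": float(np.trapezoid(tpr, fpr)),
            }
    return MetricsReport(
        confusion=cm,
        per_class=per_class,
        macro_precision=float(np.mean([v["precision"] for v in per_class.values()])),
        macro_recall=float(np.mean([v["recall"] for v in per_class.values()])),
        macro_f1=float(np.mean([v["f1"] for v in per_class.values()])),
        accuracy=float(np.trace(counts) / counts.sum()) if counts.sum() else 0.0,
        kappa=_kappa(counts),
        mcc=_mcc(counts),
        roc=roc,
    )


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings with the package defaults.

    Window length defaults to 5 s with 50% overlap and a 0.75 label-purity
    threshold; complex activity sets may warrant a longer window, so it is a
    per-dataset knob.
    """

    median_kernel: int = 3
    window_seconds: float = 5.0
    overlap_fraction: float = 0.5
    purity_threshold: float = 0.75
    features: FeatureConfig = field(default_factory=FeatureConfig)
    learning_rate: float = 0.01
    batch_size: int = 1000
    max_epochs: int = 2000
    l2: float = 1e-4
    validation_fraction: float = 0.1
    patience: int = 10
    select_k: float | int = 0.5
    classifier: str = "random_forest"
    n_trees: int = 100
    max_depth: int | None = None
    seed: int = 0


@dataclass
class LosoResult:
    """Per-fold and pooled metrics of one LOSO run."""

    fold_reports: dict[str, MetricsReport]
    pooled: MetricsReport
    fold_selected: dict[str, list[str]]
    n_windows: int

    def to_dict(self) -> dict:
        return {
            "pooled": self.pooled.to_dict(),
            "folds": {s: r.to_dict() for s, r in self.fold_reports.items()},
            "selected_features": self.fold_selected,
            "n_windows": self.n_windows,
        }


def prepare_windows(recordings: list[Recording], config: PipelineConfig) -> list[Window]:
    """Denoise every recording and segment into labelled windows."""
    windows: list[Window] = []
    for rec in recordings:
        clean = median_denoise(rec, kernel=config.median_kernel)
        windows.extend(
            segment(
                clean,
                window_seconds=config.window_seconds,
                overlap_fraction=config.overlap_fraction,
                purity_threshold=config.purity_threshold,
            )
        )
    return windows


def _assert_partition(folds, n_rows: int, subjects: np.ndarray) -> None:
    seen = np.zeros(n_rows, dtype=int)
    for train, test in folds:
        if set(subjects[train]) & set(subjects[test]):
            raise AssertionError("fold mixes subjects between train and test")
        seen[test] += 1
    if not (seen == 1).all():
        raise AssertionError("test sets do not partition the windows")


def run_loso_on_features(
    fm: FeatureMatrix,
    windows: list[Window],
    config: PipelineConfig,
    permute_train_labels: bool = False,
) -> LosoResult:
    """LOSO evaluation of an already-extracted feature matrix.

    Per fold: min-max normalize on training rows, fit the SGD ranker, keep
    the top-k features, fit the configured classifier and predict the held
    out subject.  ``permute_train_labels`` shuffles training labels within
    each fold (seeded) as a chance-level control.
    """
    folds = loso_folds(windows)
    _assert_partition(folds, fm.n_rows, fm.subject_ids)
    seeds = np.random.SeedSequence(config.seed).generate_state(4 * len(folds)) % (2**31)
    fold_reports: dict[str, MetricsReport] = {}
    fold_selected: dict[str, list[str]] = {}
    all_true: list[np.ndarray] = []
    all_pred: list[np.ndarray] = []
    all_prob: list[np.ndarray] = []
    class_list = sorted(set(fm.labels.astype(str).tolist()))
    for f, (train_idx, test_idx) in enumerate(folds):
        subject = str(fm.subject_ids[test_idx[0]])
        train_fm = fm.take(train_idx)
        test_fm = fm.take(test_idx)
        y_train = train_fm.labels.astype(str)
        if permute_train_labels:
            rng = np.random.default_rng(seeds[4 * f + 3])
            y_train = rng.permutation(y_train)
        norm_train, (norm_test,), _, _ = minmax_fit_apply(train_fm, [test_fm])
        model = sgd_fit(
            norm_train,
            labels=y_train,
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            max_epochs=config.max_epochs,
            l2=config.l2,
            validation_fraction=config.validation_fraction,
            patience=config.patience,
            seed=int(seeds[4 * f]),
        )
        ranking = rank_features(model)
        sel_train = select_top_k(norm_train, ranking, config.select_k)
        sel_test = select_top_k(norm_test, ranking, config.select_k)
        fold_selected[subject] = list(sel_train.feature_names)
        if config.classifier == "random_forest":
            forest = rf_fit(
                sel_train,
                labels=y_train,
                n_trees=config.n_trees,
                max_depth=config.max_depth,
                seed=int(seeds[4 * f + 1]),
            )
            pred, prob = rf_predict(forest, sel_test)
            fold_classes = forest.class_list
        else:
            pred, prob, fold_classes = baseline_fit_predict(
                config.classifier, sel_train, y_train, sel_test, seed=int(seeds[4 * f + 2])
            )
        # expand fold probabilities onto the global class list
        full_prob = np.zeros((prob.shape[0], len(class_list)))
        for j, c in enumerate(fold_classes):
            full_prob[:, class_list.index(c)] = prob[:, j]
        y_test = test_fm.labels.astype(str)
        fold_reports[subject] = compute_metrics(y_test, pred, full_prob, class_list)
        all_true.append(y_test)
        all_pred.append(pred)
        all_prob.append(full_prob)
    pooled = compute_metrics(
        np.concatenate(all_true), np.concatenate(all_pred), np.vstack(all_prob), class_list
    )
    assert pooled.confusion.total == fm.n_rows
    return LosoResult(
        fold_reports=fold_reports,
        pooled=pooled,
        fold_selected=fold_selected,
        n_windows=fm.n_rows,
    )


def run_loso(
    recordings: list[Recording],
    config: PipelineConfig | None = None,
    outdir: str | os.PathLike | None = None,
    permute_train_labels: bool = False,
) -> LosoResult:
    """Full pipeline: denoise, segment, extract, and LOSO-evaluate.

    Denoising, segmentation and feature extraction are stateless per window,
    so they run once; all fold-dependent fitting happens inside
    :func:`run_loso_on_features`.  When ``outdir`` is given, the pooled and
    per-fold confusion matrices (CSV), metrics (JSON) and ROC points (CSV)
    are written there.
    """
    config = config or PipelineConfig()
    windows = prepare_windows(recordings, config)
    fm = build_feature_matrix(windows, config.features)
    result = run_loso_on_features(fm, windows, config, permute_train_labels)
    if outdir is not None:
        write_loso_artifacts(result, outdir)
    return result


def write_loso_artifacts(result: LosoResult, outdir: str | os.PathLike) -> None:
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "metrics.json"), "w") as fh:
        json.dump(result.to_dict(), fh, indent=2, sort_keys=True)
    cl = result.pooled.confusion.class_list
    pd.DataFrame(result.pooled.confusion.counts, index=cl, columns=cl).to_csv(
        os.path.join(outdir, "confusion_pooled.csv")
    )
    for subject, report in result.fold_reports.items():
        pd.DataFrame(report.confusion.counts, index=cl, columns=cl).to_csv(
            os.path.join(outdir, f"confusion_{subject}.csv")
        )
    if result.pooled.roc:
        rows = []
        for c, r in result.pooled.roc.items():
            for fpr, tpr in zip(r["fpr"], r["tpr"]):
                rows.append({"class": c, "fpr": fpr, "tpr": tpr})
        pd.DataFrame(rows).to_csv(os.path.join(outdir, "roc_pooled.csv"), index=False)
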