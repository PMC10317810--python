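"""Leakage-safe cross-validated evaluation, permutation significance, and
cross-drug transferability.

The whole pipeline (binarizer + network + SVM) is refitted inside every
cross-validation fold on the nine training folds only; held-out rows are
used exclusively for prediction. Headline metrics are computed on the
pooled held-out predictions across folds (per-fold metrics are also
reported for transparency).

Significance uses a label-permutation test: the full label vector is
shuffled once per repetition (preserving class balance — the standard
exchangeable null) and the identical cross-validation is rerun; the
p-value uses the add-one (Phipson–Smyth) formula so it is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .errors import EvaluationError, SchemaMismatchError
from .features import FeatureTable
from .model import TrainedTwoStageModel, TwoStageConfig, fit_two_stage, predict

__all__ = [
    "FoldAssignment",
    "PerformanceReport",
    "PermutationResult",
    "stratified_kfold",
    "compute_metrics",
    "cross_validate",
    "permutation_test",
    "transferability",
]


@dataclass(frozen=True)
class FoldAssignment:
    """Stratified fold index per sample (0..k-1)."""

    fold_of: np.ndarray
    k: int
    seed: int

    def train_test_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = np.nonzero(self.fold_of == fold)[0]
        train = np.nonzero(self.fold_of != fold)[0]
        return train, test


def stratified_kfold(labels, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Deterministic stratified k-fold assignment.

    Fold sizes differ by at most one; per-fold class counts differ from
    proportionality by at most one subject.
    """
    labels = np.asarray(labels).astype(int)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise EvaluationError(
            f"smallest class has {counts.min()} members, fewer than k={k}; "
            "use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = np.empty(labels.shape[0], dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros_like(labels), labels)):
        fold_of[test_idx] = fold
    return FoldAssignment(fold_of, k, seed)


@dataclass
class PerformanceReport:
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    n_positive: int
    n_negative: int
    per_fold: list[dict] = field(default_factory=list)
    pooled: bool = True

    def as_dict(self) -> dict:
        return {
            "balanced_accuracy": self.balanced_accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
        }


def compute_metrics(y_true, y_pred, scores) -> PerformanceReport:
    """Balanced accuracy, sensitivity, specificity and AUC.

    Sensitivity is the true-positive rate on the responder (label 1)
    class; AUC is the probability a random positive's decision score
    exceeds a random negative's, with ties counted half.
    """
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    scores = np.asarray(scores, dtype=np.float64)
    if len(np.unique(y_true)) < 2:
        raise EvaluationError("metrics need both classes in the true labels")
    pos = y_true == 1
    neg = ~pos
    tp = int(np.sum(y_pred[pos] == 1))
    tn = int(np.sum(y_pred[neg] == 0))
    sensitivity = tp / pos.sum()
    specificity = tn / neg.sum()
    auc = float(roc_auc_score(y_true, scores))
    return PerformanceReport(
        balanced_accuracy=(sensitivity + specificity) / 2.0,
        sensitivity=float(sensitivity),
        specificity=float(specificity),
        auc=auc,
        n_positive=int(pos.sum()),
        n_negative=int(neg.sum()),
    )


def _fold_model_seed(seed: int, fold: int) -> int:
    # independent per-fold model seeds, kept below 2**31
    return int((seed * 1_000_003 + 7919 * (fold + 1)) % (2**31 - 1))


def cross_validate(
    table: FeatureTable,
    labels,
    config: TwoStageConfig,
    k: int = 10,
    seed: int = 0,
    return_models: bool = False,
) -> PerformanceReport | tuple[PerformanceReport, list[TrainedTwoStageModel], FoldAssignment]:
    """Stratified k-fold cross-validation of the two-stage pipeline.

    Every fold refits the full pipeline on its training rows only; all
    held-out predictions are pooled for the headline metrics.
    """
    labels = np.asarray(labels).astype(int)
    folds = stratified_kfold(labels, k=k, seed=seed)
    pooled_true = np.empty_like(labels)
    pooled_pred = np.empty_like(labels)
    pooled_scores = np.empty(labels.shape[0], dtype=np.float64)
    per_fold: list[dict] = []
    models: list[TrainedTwoStageModel] = []
    for fold in range(k):
        train_idx, test_idx = folds.train_test_indices(fold)
        fold_config = TwoStageConfig(
            **{**config.to_dict(), "seed": _fold_model_seed(config.seed, fold)}
        )
        model = fit_two_stage(table.select(train_idx), labels[train_idx], fold_config)
        pred, scores = predict(model, table.select(test_idx))
        pooled_true[test_idx] = labels[test_idx]
        pooled_pred[test_idx] = pred
        pooled_scores[test_idx] = scores
        fold_metrics = {"fold": fold, "n_test": int(test_idx.size)}
        if len(np.unique(labels[test_idx])) == 2:
            rep = compute_metrics(labels[test_idx], pred, scores)
            fold_metrics.update(rep.as_dict())
        per_fold.append(fold_metrics)
        if return_models:
            models.append(model)
    report = compute_metrics(pooled_true, pooled_pred, pooled_scores)
    report.per_fold = per_fold
    if return_models:
        return report, models, folds
    return report


@dataclass
class PermutationResult:
    observed_bac: float
    null_bacs: np.ndarray
    p_value: float
    n_permutations: int
    seed: int


def permutation_test(
    table: FeatureTable,
    labels,
    config: TwoStageConfig,
    n_permutations: int = 1000,
    k: int = 10,
    seed: int = 0,
    observed: Optional[PerformanceReport] = None,
) -> PermutationResult:
    """Label-permutation significance of the cross-validated accuracy.

    ``p = (1 + #{null BAC >= observed BAC}) / (n_permutations + 1)``.
    Pass a precomputed ``observed`` report to avoid refitting it.
    """
    if n_permutations < 1:
        raise EvaluationError("n_permutations must be >= 1")
    labels = np.asarray(labels).astype(int)
    if observed is None:
        observed = cross_validate(table, labels, config, k=k, seed=seed)
    rng = np.random.default_rng(seed)
    null_bacs = np.empty(n_permutations)
    for i in range(n_permutations):
        permuted = rng.permutation(labels)
        perm_seed = int(rng.integers(0, 2**31 - 1))
        perm_config = TwoStageConfig(**{**config.to_dict(), "seed": perm_seed})
        rep = cross_validate(table, permuted, perm_config, k=k, seed=perm_seed)
        null_bacs[i] = rep.balanced_accuracy
    p = (1 + int(np.sum(null_bacs >= observed.balanced_accuracy))) / (n_permutations + 1)
    return PermutationResult(
        observed_bac=observed.balanced_accuracy,
        null_bacs=null_bacs,
        p_value=p,
        n_permutations=n_permutations,
        seed=seed,
    )


def transferability(
    source_table: FeatureTable,
    source_labels,
    target_table: FeatureTable,
    target_labels,
    config: TwoStageConfig,
) -> PerformanceReport:
    """Train on one whole treatment group, evaluate on the other."""
    if list(source_table.feature_names) != list(target_table.feature_names):
        raise SchemaMismatchError("source and target tables use different schemas")
    source_labels = np.asarray(source_labels).astype(int)
    target_labels = np.asarray(target_labels).astype(int)
    for name, lab in (("source", source_labels), ("target", target_labels)):
        if len(np.unique(lab)) < 2:
            raise EvaluationError(f"{name} labels must contain both classes")
    model = fit_two_stage(source_table, source_labels, config)
    pred, scores = predict(model, target_table)
    return compute_metrics(target_labels, pred, scores)
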