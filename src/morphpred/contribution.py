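"""Feature-contribution ranking for the trained two-stage model.

Two complementary methods:

``connection_weight`` (default)
    A property of the trained encoder: the score of input feature *j* is
    the sum over last-hidden-layer units of the products of absolute
    weights along every path from *j* through the network
    (Olden/Garson-style propagation), i.e. row sums of
    ``|W1|·|W2|·…·|WL|``. Invariant to a common positive rescaling of all
    weight matrices after simplex normalization.

``permutation_importance``
    Model-agnostic: the mean drop in balanced accuracy on validation data
    when feature *j*'s column is shuffled (several repeats), negatives
    clipped to zero.

Scores are normalized onto the unit simplex so rankings are comparable
across models and methods. In the cross-validation context, contributions
are computed per fold-model and averaged before ranking, which stabilizes
small-sample rankings; a single-model mode is also available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import EvaluationError
from .evaluation import compute_metrics, cross_validate
from .features import FeatureTable
from .model import TrainedTwoStageModel, TwoStageConfig, predict

__all__ = [
    "ContributionRanking",
    "compute_contributions",
    "top_k",
    "fold_averaged_contributions",
]

METHODS = ("connection_weight", "permutation_importance")


@dataclass
class ContributionRanking:
    feature_names: list[str]
    scores: np.ndarray  # non-negative, sums to 1
    method: str
    model_kind: str = ""

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.shape[0] != len(self.feature_names):
            raise ValueError("one score per feature required")
        if np.any(self.scores < 0):
            raise ValueError("contribution scores must be non-negative")
        total = self.scores.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"scores must sum to 1 (got {total})")


def _normalize(raw: np.ndarray) -> np.ndarray:
    raw = np.clip(raw, 0.0, None)
    total = raw.sum()
    if total <= 0:
        # no feature shows any contribution: report the uninformative uniform
        return np.full(raw.shape[0], 1.0 / raw.shape[0])
    return raw / total


def _connection_weights(model: TrainedTwoStageModel) -> np.ndarray:
    if not model.encoder_weights:
        raise EvaluationError(
            "connection_weight requires at least one encoder layer"
        )
    path = np.abs(model.encoder_weights[0][0])
    for W, _ in model.encoder_weights[1:]:
        path = path @ np.abs(W)
    return path.sum(axis=1)


def _permutation_importance(
    model: TrainedTwoStageModel,
    table: FeatureTable,
    labels: np.ndarray,
    n_repeats: int,
    seed: int,
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    pred, scores = predict(model, table)
    base_bac = compute_metrics(labels, pred, scores).balanced_accuracy
    raw = np.zeros(table.n_features)
    values = table.values
    for j in range(table.n_features):
        drops = []
        for _ in range(n_repeats):
            shuffled = values.copy()
            shuffled[:, j] = rng.permutation(shuffled[:, j])
            perturbed = FeatureTable(
                list(table.subject_ids), shuffled, list(table.feature_names), table.kind
            )
            p, s = predict(model, perturbed)
            drops.append(base_bac - compute_metrics(labels, p, s).balanced_accuracy)
        raw[j] = max(0.0, float(np.mean(drops)))
    return raw


def compute_contributions(
    model: TrainedTwoStageModel,
    method: str = "connection_weight",
    validation_table: Optional[FeatureTable] = None,
    validation_labels=None,
    n_repeats: int = 5,
    seed: int = 0,
) -> ContributionRanking:
    """Rank every input feature by its contribution to the model."""
    if method not in METHODS:
        raise EvaluationError(f"unknown contribution method {method!r}")
    if method == "connection_weight":
        raw = _connection_weights(model)
    else:
        if validation_table is None or validation_labels is None:
            raise EvaluationError(
                "permutation_importance requires validation data and labels"
            )
        raw = _permutation_importance(
            model,
            validation_table,
            np.asarray(validation_labels).astype(int),
            n_repeats,
            seed,
        )
    kind = "joint" if len(model.feature_names) > 150 else ""
    return ContributionRanking(
        list(model.feature_names), _normalize(raw), method, model_kind=kind
    )


def fold_averaged_contributions(
    table: FeatureTable,
    labels,
    config: TwoStageConfig,
    method: str = "connection_weight",
    k: int = 10,
    seed: int = 0,
    n_repeats: int = 5,
) -> ContributionRanking:
    """Contributions averaged over the k cross-validation fold-models.

    For ``permutation_importance`` each fold-model is probed on its own
    held-out fold, keeping the importance estimate out-of-sample.
    """
    labels = np.asarray(labels).astype(int)
    _, models, folds = cross_validate(
        table, labels, config, k=k, seed=seed, return_models=True
    )
    scores = np.zeros(table.n_features)
    used = 0
    for fold, model in enumerate(models):
        _, test_idx = folds.train_test_indices(fold)
        if method == "permutation_importance":
            if len(np.unique(labels[test_idx])) < 2:
                continue
            ranking = compute_contributions(
                model,
                method,
                validation_table=table.select(test_idx),
                validation_labels=labels[test_idx],
                n_repeats=n_repeats,
                seed=_fold_seed(seed, fold),
            )
        else:
            ranking = compute_contributions(model, method)
        scores += ranking.scores
        used += 1
    if used == 0:
        raise EvaluationError("no fold produced a contribution estimate")
    ranking = ContributionRanking(
        list(table.feature_names), _normalize(scores / used), method,
        model_kind=table.kind,
    )
    return ranking


def _fold_seed(seed: int, fold: int) -> int:
    return int((seed * 31_337 + fold) % (2**31 - 1))


def top_k(ranking: ContributionRanking, k: int = 10) -> list[tuple[str, float]]:
    """Top-k features, descending score, ties broken by canonical order."""
    n = len(ranking.feature_names)
    if not 1 <= k <= n:
        raise EvaluationError(f"k must be in 1..{n}, got {k}")
    order = np.lexsort((np.arange(n), -ranking.scores))
    return [(ranking.feature_names[i], float(ranking.scores[i])) for i in order[:k]]
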