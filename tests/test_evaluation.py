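"""Cross-validation, metrics, permutation test and transferability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphpred import (
    FeatureTable,
    TwoStageConfig,
    compute_metrics,
    cross_validate,
    fit_two_stage,
    permutation_test,
    predict,
    stratified_kfold,
    transferability,
)
from morphpred.errors import EvaluationError
from morphpred.model import save_model
from tests.test_model import two_cluster_table


@pytest.fixture
def toy_cfg():
    """Small config compatible with the low-dimensional toy tables."""
    return TwoStageConfig(
        layer_sizes=(5, 3), pretrain_epochs=3, finetune_epochs=15,
        learning_rate=0.3, batch_size=16, seed=0,
    )


class TestStratifiedKFold:
    def test_balanced_divisible_case_exact(self):
        labels = np.array([0] * 50 + [1] * 50)
        folds = stratified_kfold(labels, k=10, seed=0)
        for fold in range(10):
            _, test = folds.train_test_indices(fold)
            assert test.size == 10
            assert labels[test].sum() == 5

    def test_partition_property(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, size=47)
        while min(np.bincount(labels)) < 5:
            labels = rng.integers(0, 2, size=47)
        folds = stratified_kfold(labels, k=5, seed=3)
        seen = np.concatenate(
            [folds.train_test_indices(f)[1] for f in range(5)]
        )
        assert sorted(seen.tolist()) == list(range(47))

    def test_stratification_within_one_subject(self):
        labels = np.array([0] * 23 + [1] * 31)
        folds = stratified_kfold(labels, k=5, seed=2)
        overall = labels.mean()
        for fold in range(5):
            _, test = folds.train_test_indices(fold)
            expected_pos = overall * test.size
            assert abs(labels[test].sum() - expected_pos) <= 1

    def test_determinism(self):
        labels = np.array([0, 1] * 20)
        a = stratified_kfold(labels, k=4, seed=9)
        b = stratified_kfold(labels, k=4, seed=9)
        np.testing.assert_array_equal(a.fold_of, b.fold_of)

    def test_class_smaller_than_k_rejected(self):
        labels = np.array([0] * 20 + [1] * 3)
        with pytest.raises(EvaluationError, match="smaller k"):
            stratified_kfold(labels, k=5)


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 0, 1, 1])
        rep = compute_metrics(y, y, np.array([-1.0, -2.0, 1.0, 2.0]))
        assert rep.balanced_accuracy == 1.0
        assert rep.auc == 1.0

    def test_degenerate_all_positive_predictor(self):
        y = np.array([1] * 3 + [0] * 7)
        pred = np.ones(10, dtype=int)
        rep = compute_metrics(y, pred, np.ones(10))
        assert rep.sensitivity == 1.0
        assert rep.specificity == 0.0
        assert rep.balanced_accuracy == 0.5

    def test_auc_worked_example(self):
        # pos scores 0.9, 0.8; neg scores 0.85, 0.1 -> 3 of 4 pairs won
        y = np.array([1, 1, 0, 0])
        scores = np.array([0.9, 0.8, 0.85, 0.1])
        rep = compute_metrics(y, np.array([1, 1, 0, 0]), scores)
        assert rep.auc == pytest.approx(0.75)

    def test_bac_identity_with_sens_spec(self):
        y = np.array([1, 1, 1, 0, 0])
        pred = np.array([1, 0, 1, 0, 1])
        rep = compute_metrics(y, pred, pred.astype(float))
        assert rep.balanced_accuracy == pytest.approx(
            (rep.sensitivity + rep.specificity) / 2
        )

    def test_relabel_symmetry_swaps_sens_spec(self):
        y = np.array([1, 1, 0, 0, 0, 1])
        pred = np.array([1, 0, 0, 1, 0, 1])
        scores = np.array([2.0, -0.5, -1.0, 0.5, -2.0, 1.0])
        a = compute_metrics(y, pred, scores)
        b = compute_metrics(1 - y, 1 - pred, -scores)
        assert a.sensitivity == pytest.approx(b.specificity)
        assert a.specificity == pytest.approx(b.sensitivity)
        assert a.balanced_accuracy == pytest.approx(b.balanced_accuracy)

    def test_single_class_truth_rejected(self):
        with pytest.raises(EvaluationError):
            compute_metrics(np.ones(4), np.ones(4), np.ones(4))

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(4, 30))
    def test_auc_equals_pairwise_win_rate(self, seed, n):
        """AUC must equal the brute-force pairwise comparison oracle."""
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, size=n)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        scores = np.round(rng.normal(size=n), 1)  # ties likely
        rep = compute_metrics(y, y, scores)
        pos = scores[y == 1]
        neg = scores[y == 0]
        wins = sum(
            1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg
        )
        assert rep.auc == pytest.approx(wins / (pos.size * neg.size))


class TestCrossValidate:
    def test_fold_models_never_see_their_test_rows(self, tmp_path):
        table, labels = two_cluster_table(n=40, seed=20)
        config = TwoStageConfig(
            layer_sizes=(4,), pretrain_epochs=3, finetune_epochs=5, seed=0
        )
        _, models, folds = cross_validate(
            table, labels, config, k=4, seed=1, return_models=True
        )
        # perturb fold-0's held-out rows; fold-0's model must be unchanged
        _, test0 = folds.train_test_indices(0)
        perturbed_values = table.values.copy()
        perturbed_values[test0] *= 3.0
        perturbed = FeatureTable(
            table.subject_ids, perturbed_values, table.feature_names, table.kind
        )
        _, models_p, _ = cross_validate(
            perturbed, labels, config, k=4, seed=1, return_models=True
        )
        a, b = tmp_path / "a.npz", tmp_path / "b.npz"
        save_model(models[0], a)
        save_model(models_p[0], b)
        assert a.read_bytes() == b.read_bytes()

    def test_strong_signal_recovered(self, toy_cfg):
        table, labels = two_cluster_table(n=60, dim=10, separation=3.0, seed=21)
        rep = cross_validate(table, labels, toy_cfg, k=5, seed=0)
        assert rep.balanced_accuracy >= 0.85

    def test_per_fold_reports_present(self, toy_cfg):
        table, labels = two_cluster_table(n=40, seed=22)
        rep = cross_validate(table, labels, toy_cfg, k=4, seed=0)
        assert len(rep.per_fold) == 4
        assert rep.pooled


class TestPermutationTest:
    def test_add_one_bound_and_formula(self, toy_cfg):
        table, labels = two_cluster_table(n=30, dim=8, seed=23)
        result = permutation_test(
            table, labels, toy_cfg, n_permutations=9, k=3, seed=0
        )
        expected = (1 + np.sum(result.null_bacs >= result.observed_bac)) / 10
        assert result.p_value == pytest.approx(expected)
        assert result.p_value >= 1 / 10

    def test_strong_signal_is_significant(self, toy_cfg):
        table, labels = two_cluster_table(n=40, dim=10, separation=4.0, seed=24)
        result = permutation_test(
            table, labels, toy_cfg, n_permutations=19, k=4, seed=0
        )
        assert result.p_value == pytest.approx(1 / 20)

    def test_zero_permutations_rejected(self, toy_cfg):
        table, labels = two_cluster_table(seed=25)
        with pytest.raises(EvaluationError):
            permutation_test(table, labels, toy_cfg, n_permutations=0)


class TestTransferability:
    def test_resubstitution_equals_training_performance(self, toy_cfg):
        table, labels = two_cluster_table(n=30, seed=26)
        rep = transferability(table, labels, table, labels, toy_cfg)
        model = fit_two_stage(table, labels, toy_cfg)
        pred, scores = predict(model, table)
        direct = compute_metrics(labels, pred, scores)
        assert rep.balanced_accuracy == pytest.approx(direct.balanced_accuracy)
        assert rep.auc == pytest.approx(direct.auc)

    def test_schema_mismatch_rejected(self, toy_cfg):
        a, labels = two_cluster_table(n=20, dim=6, seed=27)
        b, labels_b = two_cluster_table(n=20, dim=7, seed=28)
        from morphpred.errors import SchemaMismatchError

        with pytest.raises(SchemaMismatchError):
            transferability(a, labels, b, labels_b, toy_cfg)
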