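"""The two-stage classifier: binarization, pre-training, fine-tuning,
representations, SVM composition, serialization, leakage and determinism."""

import numpy as np
import pytest
from sklearn.svm import SVC

from morphpred import (
    FeatureTable,
    TwoStageConfig,
    fit_two_stage,
    load_model,
    predict,
    save_model,
)
from morphpred.errors import ConfigError, SchemaMismatchError
from morphpred.model import (
    apply_binarizer,
    extract_representations,
    finetune_network,
    fit_binarizer,
    pretrain_stacked_autoencoders,
)
from morphpred.schema import make_custom_schema
from tests.conftest import make_table


def toy_table(values, kind="baseline"):
    values = np.asarray(values, dtype=float)
    names = [f"f{i}" for i in range(values.shape[1])]
    ids = [f"s{i}" for i in range(values.shape[0])]
    return FeatureTable(ids, values, names, kind)


def two_cluster_table(n=40, dim=12, separation=6.0, seed=0):
    """Two well-separated clusters; labels by cluster."""
    rng = np.random.default_rng(seed)
    half = n // 2
    a = rng.normal(10.0, 1.0, size=(half, dim))
    b = rng.normal(10.0 + separation, 1.0, size=(n - half, dim))
    values = np.vstack([a, b])
    labels = np.array([0] * half + [1] * (n - half))
    perm = rng.permutation(n)
    return toy_table(values[perm]), labels[perm]


class TestBinarizer:
    def test_median_threshold_arithmetic(self):
        table = toy_table([[1.0], [2.0], [3.0], [4.0]])
        state = fit_binarizer(table, "median_split")
        assert state.thresholds[0] == pytest.approx(2.5)

    def test_median_split_balance_on_training_rows(self):
        table = make_table(make_custom_schema(
            [(f"r{i}", "left", "area") for i in range(5)]), 20, seed=1)
        state = fit_binarizer(table, "median_split")
        binary = apply_binarizer(state, table)
        frac = binary.mean(axis=0)
        assert np.all((frac >= 0.25) & (frac <= 0.75))
        # distinct values, even n: exactly half above the median
        assert np.allclose(frac, 0.5)

    def test_values_equal_to_threshold_map_to_zero(self):
        train = toy_table([[1.0, 5.0], [3.0, 7.0]])
        state = fit_binarizer(train, "median_split")
        at_threshold = toy_table([[2.0, 6.0]])
        np.testing.assert_array_equal(
            apply_binarizer(state, at_threshold), [[0.0, 0.0]]
        )

    def test_median_split_invariant_to_monotone_transform(self):
        table = make_table(make_custom_schema(
            [("r", "left", "area")]), 15, seed=2)
        state = fit_binarizer(table, "median_split")
        cubed = FeatureTable(
            table.subject_ids, table.values**3, table.feature_names, "baseline"
        )
        state_cubed = fit_binarizer(cubed, "median_split")
        np.testing.assert_array_equal(
            apply_binarizer(state, table), apply_binarizer(state_cubed, cubed)
        )

    def test_minmax_clips_out_of_range(self):
        train = toy_table([[10.0], [20.0]])
        state = fit_binarizer(train, "minmax_sigmoid")
        out = apply_binarizer(state, toy_table([[5.0], [15.0], [25.0]]))
        np.testing.assert_allclose(out.ravel(), [0.0, 0.5, 1.0])

    def test_output_in_unit_interval(self):
        table = make_table(make_custom_schema(
            [(f"r{i}", "left", "volume") for i in range(4)]), 10, seed=3)
        for method in ("median_split", "minmax_sigmoid"):
            out = apply_binarizer(fit_binarizer(table, method), table)
            assert out.min() >= 0.0 and out.max() <= 1.0

    def test_constant_feature_warns(self):
        table = toy_table([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
        with pytest.warns(UserWarning, match="constant"):
            fit_binarizer(table, "median_split")

    def test_schema_mismatch_rejected(self):
        state = fit_binarizer(toy_table([[1.0], [2.0]]), "median_split")
        other = FeatureTable(["a"], [[1.0]], ["different"], "baseline")
        with pytest.raises(SchemaMismatchError):
            apply_binarizer(state, other)


class TestPretraining:
    def make_binary(self, n=30, dim=20, seed=0):
        rng = np.random.default_rng(seed)
        return (rng.random((n, dim)) > 0.5).astype(float)

    def test_reconstruction_loss_decreases(self):
        config = TwoStageConfig(layer_sizes=(8, 4), pretrain_epochs=30, seed=0)
        _, histories = pretrain_stacked_autoencoders(self.make_binary(), config)
        for history in histories:
            assert history[-1] <= history[0]

    def test_identical_rows_give_identical_codes(self):
        x = np.tile((np.arange(20) % 2).astype(float), (10, 1))
        config = TwoStageConfig(layer_sizes=(6,), pretrain_epochs=20, seed=1)
        weights, _ = pretrain_stacked_autoencoders(x, config)
        from morphpred.model import forward_activations

        codes = forward_activations(weights, x)[-1]
        assert np.allclose(codes, codes[0])

    def test_same_seed_identical_weights(self):
        x = self.make_binary(seed=2)
        config = TwoStageConfig(layer_sizes=(8, 4), pretrain_epochs=10, seed=7)
        w1, _ = pretrain_stacked_autoencoders(x, config)
        w2, _ = pretrain_stacked_autoencoders(x, config)
        for (a, ab), (b, bb) in zip(w1, w2):
            np.testing.assert_array_equal(a, b)
            np.testing.assert_array_equal(ab, bb)


class TestFinetuning:
    def test_separable_clusters_reach_high_training_accuracy(self):
        table, labels = two_cluster_table(seed=3)
        config = TwoStageConfig(
            layer_sizes=(8, 4), pretrain_epochs=20, finetune_epochs=100, seed=0
        )
        model = fit_two_stage(table, labels, config)
        pred, _ = predict(model, table)
        assert (pred == labels).mean() >= 0.95

    def test_label_flip_flips_decisions(self):
        table, labels = two_cluster_table(seed=4)
        config = TwoStageConfig(
            layer_sizes=(8, 4), pretrain_epochs=20, finetune_epochs=100, seed=0
        )
        pred_a, _ = predict(fit_two_stage(table, labels, config), table)
        pred_b, _ = predict(fit_two_stage(table, 1 - labels, config), table)
        assert (pred_a == 1 - pred_b).mean() >= 0.9

    def test_single_class_rejected(self):
        x = np.random.default_rng(0).random((10, 5))
        config = TwoStageConfig(layer_sizes=(3,))
        with pytest.raises(ConfigError, match="both classes"):
            finetune_network([], x, np.zeros(10, dtype=int), config)


class TestRepresentations:
    def test_width_and_range(self):
        table, labels = two_cluster_table(seed=5)
        config = TwoStageConfig(
            layer_sizes=(8, 3), pretrain_epochs=5, finetune_epochs=10, seed=0
        )
        model = fit_two_stage(table, labels, config)
        binary = apply_binarizer(model.binarizer_state, table)
        reps = extract_representations(model, binary)
        assert reps.shape == (table.n_subjects, 3)
        assert reps.min() > 0.0 and reps.max() < 1.0

    def test_identical_inputs_identical_rows(self):
        table, labels = two_cluster_table(seed=6)
        config = TwoStageConfig(
            layer_sizes=(4,), pretrain_epochs=5, finetune_epochs=5, seed=0
        )
        model = fit_two_stage(table, labels, config)
        row = apply_binarizer(model.binarizer_state, table)[0]
        reps = extract_representations(model, np.vstack([row, row]))
        np.testing.assert_array_equal(reps[0], reps[1])


class TestFitPredict:
    def test_compression_invariant_rejects_wide_layers(self):
        table, labels = two_cluster_table(dim=6, seed=7)
        with pytest.raises(ConfigError, match="smaller than the input"):
            fit_two_stage(table, labels, TwoStageConfig(layer_sizes=(6,)))

    def test_predict_on_train_matches_svm_training_predictions(self):
        table, labels = two_cluster_table(seed=8)
        config = TwoStageConfig(
            layer_sizes=(8, 4), pretrain_epochs=10, finetune_epochs=30, seed=0
        )
        model = fit_two_stage(table, labels, config)
        pred, scores = predict(model, table)
        binary = apply_binarizer(model.binarizer_state, table)
        reps = extract_representations(model, binary)
        np.testing.assert_array_equal(pred, model.svm_state.predict_labels(reps))
        np.testing.assert_array_equal(scores, model.svm_state.decision(reps))

    def test_single_row_prediction(self):
        table, labels = two_cluster_table(seed=9)
        config = TwoStageConfig(
            layer_sizes=(4,), pretrain_epochs=5, finetune_epochs=10, seed=0
        )
        model = fit_two_stage(table, labels, config)
        single = table.select([0])
        pred, scores = predict(model, single)
        assert pred.shape == (1,) and scores.shape == (1,)

    def test_fit_is_deterministic(self):
        table, labels = two_cluster_table(seed=10)
        config = TwoStageConfig(
            layer_sizes=(8, 4), pretrain_epochs=10, finetune_epochs=20, seed=3
        )
        m1 = fit_two_stage(table, labels, config)
        m2 = fit_two_stage(table, labels, config)
        for (a, _), (b, _) in zip(m1.encoder_weights, m2.encoder_weights):
            np.testing.assert_array_equal(a, b)
        _, s1 = predict(m1, table)
        _, s2 = predict(m2, table)
        np.testing.assert_array_equal(s1, s2)

    @pytest.mark.parametrize("kernel", ["linear", "rbf"])
    def test_serialization_round_trip_bitwise(self, tmp_path, kernel):
        table, labels = two_cluster_table(seed=11)
        config = TwoStageConfig(
            layer_sizes=(8, 4),
            pretrain_epochs=5,
            finetune_epochs=10,
            svm_kernel=kernel,
            seed=0,
        )
        model = fit_two_stage(table, labels, config)
        path = tmp_path / "model.npz"
        save_model(model, path)
        restored = load_model(path)
        p1, s1 = predict(model, table)
        p2, s2 = predict(restored, table)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(s1, s2)  # bitwise

    def test_no_leakage_from_unseen_rows(self, tmp_path):
        """Fitted state is a function of training rows only."""
        table, labels = two_cluster_table(n=30, seed=12)
        config = TwoStageConfig(
            layer_sizes=(4,), pretrain_epochs=5, finetune_epochs=10, seed=0
        )
        model = fit_two_stage(table, labels, config)
        p1 = tmp_path / "a.npz"
        save_model(model, p1)
        # refit after perturbing rows the model never saw
        model2 = fit_two_stage(table, labels, config)
        p2 = tmp_path / "b.npz"
        save_model(model2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_degenerate_config_equals_plain_svm(self):
        """Encoder disabled + minmax squashing reduces to an SVM on
        squashed raw features (dual-route regression check)."""
        table, labels = two_cluster_table(n=30, dim=8, separation=2.0, seed=13)
        config = TwoStageConfig(
            layer_sizes=(),
            pretrain_epochs=0,
            finetune_epochs=0,
            binarization="minmax_sigmoid",
            seed=0,
        )
        model = fit_two_stage(table, labels, config)
        pred, _ = predict(model, table)

        state = fit_binarizer(table, "minmax_sigmoid")
        squashed = apply_binarizer(state, table)
        svc = SVC(kernel="linear", C=1.0, class_weight="balanced").fit(
            squashed, labels
        )
        np.testing.assert_array_equal(pred, svc.predict(squashed))
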