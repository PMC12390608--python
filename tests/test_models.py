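import numpy as np
import pytest

from erpauth import nn
from erpauth.models import (ClassicalSpec, CNNSpec, build_cnn,
                            count_trainable_parameters, predict_labels,
                            predict_scores, stratified_split,
                            train_classifier)


def blobs(rng, n_per_class=20, n_classes=2, width=30, sep=8.0):
    """Well-separated Gaussian blobs, one per class."""
    centers = rng.standard_normal((n_classes, width)) * sep
    X = np.concatenate([centers[c] + rng.standard_normal((n_per_class, width))
                        for c in range(n_classes)])
    y = np.repeat([f"c{c}" for c in range(n_classes)], n_per_class)
    return X, y


class TestStratifiedSplit:
    def test_per_class_eighty_twenty(self, rng):
        X = rng.standard_normal((100, 4))
        y = np.repeat([f"k{i}" for i in range(10)], 10)
        tr, te = stratified_split(X, y, seed=0)
        assert len(tr) == 80 and len(te) == 20
        for k in np.unique(y):
            assert (y[tr] == k).sum() == 8
            assert (y[te] == k).sum() == 2
        assert len(np.intersect1d(tr, te)) == 0

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((40, 3))
        y = np.repeat(["a", "b"], 20)
        assert np.array_equal(stratified_split(X, y, seed=7)[0],
                              stratified_split(X, y, seed=7)[0])

    def test_singleton_class_rejected(self, rng):
        X = rng.standard_normal((3, 2))
        with pytest.raises(ValueError):
            stratified_split(X, np.array(["a", "a", "b"]), seed=0)


class TestParameterCounting:
    def test_toy_conv_has_sixteen_params(self):
        # 4 filters x (3 taps x 1 channel + bias) = 16
        net = nn.Sequential([nn.Conv1D(1, 4, 3, np.random.default_rng(0))])
        assert count_trainable_parameters(net) == 16

    def test_dense_256_to_128(self):
        net = nn.Sequential([nn.Dense(256, 128, np.random.default_rng(0))])
        assert count_trainable_parameters(net) == 256 * 128 + 128

    def test_output_head_for_36_classes(self):
        net = nn.Sequential([nn.Dense(128, 36, np.random.default_rng(0))])
        assert count_trainable_parameters(net) == 128 * 36 + 36

    def test_empty_model_has_zero(self):
        assert count_trainable_parameters(nn.Sequential([])) == 0

    def test_batch_norm_counts_scale_and_shift_only(self):
        net = nn.Sequential([nn.BatchNorm1D(64)])
        assert count_trainable_parameters(net) == 128


class TestBuildCnn:
    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            build_cnn(1)
        with pytest.raises(ValueError):
            build_cnn(4, input_len=4)

    def test_default_architecture_block_structure(self):
        model = build_cnn(36, input_len=287)
        kinds = [k for k, _ in model.layer_summary]
        assert kinds.count("conv1d") == 3
        assert kinds.count("max_pool") == 2
        convs = [cfg["filters"] for k, cfg in model.layer_summary
                 if k == "conv1d"]
        assert convs == [64, 128, 256]

    def test_parameter_count_is_reproducible_closed_form(self):
        spec = CNNSpec()
        model = build_cnn(36, input_len=287, spec=spec)
        # closed-form: conv params + BN + dense stack on the pooled length
        length = 287
        total, in_ch = 0, 1
        for filt, pool in zip(spec.conv_filters, spec.pool_after):
            total += filt * (in_ch * spec.kernel_size + 1)  # conv W+b
            total += 2 * filt                               # BN gamma/beta
            if pool:
                length //= spec.pool_size
            in_ch = filt
        width = in_ch * length
        for units in spec.dense_units:
            total += width * units + units
            width = units
        total += width * 36 + 36
        assert model.n_parameters() == total


class TestTraining:
    def test_rf_separable_blobs_train_accuracy_one(self, rng):
        X, y = blobs(rng, n_per_class=20, n_classes=2)
        model = train_classifier(X, y, ClassicalSpec("rf"), seed=0)
        assert (predict_labels(model, X) == y).mean() == 1.0

    def test_knn_nearest_cluster_wins(self, rng):
        X = np.array([[0.0, 0], [0.1, 0], [-0.1, 0],
                      [10.0, 0], [10.1, 0], [9.9, 0]])
        y = np.array(["a"] * 3 + ["b"] * 3)
        model = train_classifier(X, y, "knn", seed=0)
        assert predict_labels(model, np.array([[9.8, 0.0]]))[0] == "b"

    def test_classical_determinism_under_fixed_seed(self, rng):
        X, y = blobs(rng, n_per_class=15, n_classes=3, sep=2.0)
        p1 = predict_scores(train_classifier(X, y, "rf", seed=3), X)
        p2 = predict_scores(train_classifier(X, y, "rf", seed=3), X)
        np.testing.assert_array_equal(p1, p2)

    def test_scores_are_probabilities(self, rng):
        X, y = blobs(rng, n_per_class=10, n_classes=3)
        for kind in ("rf", "lr", "nb"):   # CNN covered separately below
            model = train_classifier(X, y, kind, seed=0)
            s = predict_scores(model, X)
            np.testing.assert_allclose(s.sum(axis=1), 1.0, atol=1e-6)
            assert s.shape == (len(y), 3)

    def test_width_mismatch_rejected(self, rng):
        X, y = blobs(rng)
        model = train_classifier(X, y, "dt", seed=0)
        with pytest.raises(ValueError):
            predict_scores(model, X[:, :-1])

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 5))
        with pytest.raises(ValueError):
            train_classifier(X, np.array(["a"] * 10), "rf", seed=0)

    def test_standardizer_fit_on_training_data(self, rng):
        X, y = blobs(rng, n_per_class=25, n_classes=2)
        model = train_classifier(X, y, "lr", seed=0)
        Z = model.standardize(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-10)


@pytest.fixture(scope="module")
def tiny_cnn_fit():
    rng = np.random.default_rng(7)
    X, y = blobs(rng, n_per_class=20, n_classes=3, width=32, sep=5.0)
    spec = CNNSpec(conv_filters=(8, 12, 16), conv_dropout=(0.1, 0.1, 0.1),
                   dense_units=(16, 8), dense_dropout=0.1, max_epochs=60,
                   patience=10)
    model = train_classifier(X, y, spec, seed=7)
    return X, y, model


class TestCnnTraining:
    def test_learns_separable_blobs(self, tiny_cnn_fit):
        X, y, model = tiny_cnn_fit
        assert (predict_labels(model, X) == y).mean() >= 0.9

    def test_history_recorded_and_bounded(self, tiny_cnn_fit):
        _, _, model = tiny_cnn_fit
        h = model.history
        assert h is not None and 1 <= len(h) <= 60
        assert set(h.columns) >= {"epoch", "train_loss", "train_acc",
                                  "val_loss", "val_acc"}
        assert np.isfinite(h["val_loss"]).all()

    def test_restore_best_contract(self, tiny_cnn_fit):
        # the restored network's val loss equals the best epoch seen
        X, y, model = tiny_cnn_fit
        assert model.history["val_loss"].min() <= \
            model.history["val_loss"].iloc[-1] + 1e-12

    def test_softmax_rows_sum_to_one(self, tiny_cnn_fit):
        X, _, model = tiny_cnn_fit
        s = predict_scores(model, X)
        np.testing.assert_allclose(s.sum(axis=1), 1.0, atol=1e-6)

    def test_cnn_determinism_under_fixed_seed(self, rng):
        X, y = blobs(rng, n_per_class=8, n_classes=2, width=16, sep=5.0)
        spec = CNNSpec(conv_filters=(4, 4, 4), conv_dropout=(0.1,) * 3,
                       dense_units=(8, 8), max_epochs=5, patience=5)
        p1 = predict_scores(train_classifier(X, y, spec, seed=11), X)
        spec2 = CNNSpec(conv_filters=(4, 4, 4), conv_dropout=(0.1,) * 3,
                        dense_units=(8, 8), max_epochs=5, patience=5)
        p2 = predict_scores(train_classifier(X, y, spec2, seed=11), X)
        np.testing.assert_array_equal(p1, p2)
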