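import numpy as np
import pytest

import radtexnet as rt
from radtexnet.training import (
    AugmentSpec, ConfusionMatrix, TrainSpec, _random_affine, augment,
    compute_metrics, confusion_from_scores, cross_validate, pooled_auc,
    train_model, desk_scale_train_spec,
)

from oracles import mann_whitney_auc


class TestAugment:
    def test_zero_probabilities_are_identity(self, rng):
        x = rng.standard_normal((2, 8, 8, 4))
        spec = AugmentSpec(flip_prob=0, noise_prob=0, affine_prob=0)
        np.testing.assert_array_equal(augment(x, spec, rng), x)

    def test_certain_flip_is_involution(self, rng):
        x = np.zeros((1, 6, 6, 4))
        x[0, 1, 2, 3] = 1.0  # asymmetric phantom
        spec = AugmentSpec(flip_prob=1.0, flip_axes=(0,), noise_prob=0, affine_prob=0)
        once = augment(x, spec, np.random.default_rng(0))
        np.testing.assert_array_equal(once, np.flip(x, axis=1))
        twice = augment(once, spec, np.random.default_rng(0))
        np.testing.assert_array_equal(twice, x)

    def test_affine_shares_one_spatial_map_across_channels(self):
        """Both channels of a coordinate-grid input receive the identical
        displacement field."""
        grid = np.indices((8, 8, 4)).astype(float)[0]
        x = np.stack([grid, grid])  # identical channels
        spec = AugmentSpec(flip_prob=0, noise_prob=0, affine_prob=1.0)
        out = augment(x, spec, np.random.default_rng(3))
        np.testing.assert_allclose(out[0], out[1], atol=1e-12)
        assert not np.allclose(out[0], grid)  # the transform actually moved voxels

    def test_affine_matrix_is_rotation_over_scale(self):
        spec = AugmentSpec()
        m, off = _random_affine((8, 8, 4), spec, np.random.default_rng(1))
        # in-plane 2x2 block is scale^-1 times a rotation: orthogonal columns
        block = m[:2, :2]
        prod = block.T @ block
        assert prod[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert m[2, 2] == pytest.approx(m[2, 2])


class TestMetrics:
    def test_perfect_classifier_all_ones(self):
        m = compute_metrics(ConfusionMatrix(tp=10, tn=10, fp=0, fn=0))
        assert all(v == pytest.approx(1.0) for v in m.values())

    def test_hand_evaluated_counts(self):
        m = compute_metrics(ConfusionMatrix(tp=8, fn=2, tn=6, fp=4))
        assert m["sensitivity"] == pytest.approx(0.8)
        assert m["specificity"] == pytest.approx(0.6)
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["accuracy"] == pytest.approx(0.7)
        assert m["f1"] == pytest.approx(0.72727272, abs=1e-6)

    def test_swapping_positive_class_swaps_sensitivity_specificity(self):
        cm = ConfusionMatrix(tp=8, fn=2, tn=6, fp=4)
        swapped = ConfusionMatrix(tp=cm.tn, fn=cm.fp, tn=cm.tp, fp=cm.fn)
        m, ms = compute_metrics(cm), compute_metrics(swapped)
        assert m["sensitivity"] == pytest.approx(ms["specificity"])
        assert m["specificity"] == pytest.approx(ms["sensitivity"])

    def test_zero_denominator_reported_as_nan(self):
        m = compute_metrics(ConfusionMatrix(tp=0, tn=5, fp=0, fn=0))
        assert np.isnan(m["sensitivity"]) and np.isnan(m["precision"])

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionMatrix(tp=0, tn=0, fp=0, fn=0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, tn=0, fp=0, fn=1)


class TestAUC:
    def test_trapezoidal_auc_equals_mann_whitney(self, rng):
        for _ in range(5):
            scores = rng.random(40)
            labels = rng.integers(0, 2, 40)
            if labels.min() == labels.max():
                continue
            assert pooled_auc(scores, labels) == pytest.approx(
                mann_whitney_auc(scores, labels), abs=1e-10)

    def test_random_scores_give_chance_auc(self):
        """Pooled ROC of random scoring hovers at 0.5 over 20 seeds."""
        aucs = []
        for seed in range(20):
            g = np.random.default_rng(seed)
            labels = np.repeat([0, 1], 50)
            aucs.append(pooled_auc(g.random(100), labels))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)


def _separable_dataset(rng, n=10, shape=(16, 16, 8)):
    """Phantom-free separable volumes: class 1 brighter in one quadrant."""
    X = rng.standard_normal((2 * n, 1, *shape)) * 0.1
    y = np.array([1] * n + [0] * n)
    X[:n, :, : shape[0] // 2] += 1.0
    return X, y


class TestTraining:
    def test_loss_decreases_on_separable_data(self, rng):
        X, y = _separable_dataset(rng, n=8)
        cfg = rt.EnsembleConfig(input_channels=1, input_shape=(16, 16, 8),
                                cnn_filters=(4, 8), cnn_feature_dim=8,
                                vit_patch_edge=8, vit_depth=1, vit_dim=8,
                                vit_heads=2, fusion="concat")
        model, hist = train_model(X, y, cfg, desk_scale_train_spec(seed=0, epochs=5))
        assert hist.train_loss[-1] < hist.train_loss[0]
        assert len(hist.train_loss) == len(hist.val_loss) == 5

    def test_same_seed_reproduces_identical_loss_curves(self, rng):
        X, y = _separable_dataset(rng, n=6)
        cfg = rt.EnsembleConfig(input_channels=1, input_shape=(16, 16, 8),
                                cnn_filters=(4,), cnn_feature_dim=8,
                                fusion="cnn_only")
        spec = TrainSpec(learning_rate=1e-3, epochs=3, batch_size=4,
                         augment=True, seed=9)
        _, h1 = train_model(X, y, cfg, spec)
        _, h2 = train_model(X, y, cfg, spec)
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss

    def test_single_class_dataset_rejected(self, rng):
        X = rng.standard_normal((4, 1, 16, 16, 8))
        cfg = rt.EnsembleConfig(input_channels=1, input_shape=(16, 16, 8),
                                cnn_filters=(4,), cnn_feature_dim=8, fusion="cnn_only")
        with pytest.raises(ValueError):
            train_model(X, np.ones(4), cfg, TrainSpec())


class TestCrossValidate:
    def test_every_volume_in_exactly_one_validation_fold(self, rng):
        X, y = _separable_dataset(rng, n=6)
        cfg = rt.EnsembleConfig(input_channels=1, input_shape=(16, 16, 8),
                                cnn_filters=(4,), cnn_feature_dim=6, fusion="cnn_only")
        spec = desk_scale_train_spec(seed=0, epochs=2)
        res = cross_validate(X, y, cfg, spec, k=3, seed=0)
        # pooled scores were filled once per volume and confusion counts add up
        assert res.pooled_confusion.total == len(y)
        assert len(res.fold_confusions) == 3
        assert sum(c.total for c in res.fold_confusions) == len(y)

    def test_metrics_agree_with_recomputation_from_pooled_scores(self, rng):
        X, y = _separable_dataset(rng, n=6)
        cfg = rt.EnsembleConfig(input_channels=1, input_shape=(16, 16, 8),
                                cnn_filters=(4,), cnn_feature_dim=6, fusion="cnn_only")
        res = cross_validate(X, y, cfg, desk_scale_train_spec(seed=0, epochs=2),
                             k=2, seed=1)
        cm = confusion_from_scores(res.pooled_scores, res.pooled_labels)
        assert compute_metrics(cm) == res.pooled_metrics
        assert res.combined_auc == pytest.approx(
            mann_whitney_auc(res.pooled_scores, res.pooled_labels), abs=1e-10)

    def test_k_below_two_rejected(self, rng):
        X, y = _separable_dataset(rng, n=4)
        cfg = rt.EnsembleConfig(input_channels=1, input_shape=(16, 16, 8),
                                cnn_filters=(4,), cnn_feature_dim=6, fusion="cnn_only")
        with pytest.raises(ValueError):
            cross_validate(X, y, cfg, TrainSpec(), k=1)
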