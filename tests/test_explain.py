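import dataclasses

import numpy as np
import pytest
from scipy import ndimage

import radtexnet as rt
from radtexnet.explain import attention_rollout, hirescam, overlay, rollout_from_model
from radtexnet.networks import EnsembleModel
from radtexnet.preprocess import CTVolume

from oracles import naive_rollout


class TestAttentionRollout:
    def test_single_uniform_layer_closed_form(self):
        n = 6
        A = np.full((n, n), 1.0 / n)
        R = attention_rollout([A]).values
        # (A + I) row-normalized: diagonal (1/n + 1)/2, off-diagonal 1/(2n)
        expected = (A + np.eye(n)) / 2.0
        np.testing.assert_allclose(R, expected, atol=1e-12)

    def test_identity_attention_is_fixed_point(self):
        for depth in (1, 3, 5):
            R = attention_rollout([np.eye(7)] * depth).values
            np.testing.assert_allclose(R, np.eye(7), atol=1e-12)

    def test_three_random_layers_match_product_oracle(self, rng):
        mats = [m / m.sum(axis=1, keepdims=True) for m in rng.random((3, 9, 9))]
        for normalize in (True, False):
            got = attention_rollout(mats, normalize=normalize).values
            want = naive_rollout(mats, normalize=normalize)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_rollout_stays_row_stochastic(self, rng):
        mats = [m / m.sum(axis=1, keepdims=True) for m in rng.random((4, 8, 8))]
        R = attention_rollout(mats).values
        np.testing.assert_allclose(R.sum(axis=1), 1.0, atol=1e-12)

    def test_head_averaging_and_grid_readout(self, tiny_cfg, rng):
        model = EnsembleModel(tiny_cfg, seed=0)
        x = rng.standard_normal((1, 2, 16, 16, 8))
        amap = rollout_from_model(model, x)
        assert amap.values.shape == (16, 16, 8)
        assert np.all(np.isfinite(amap.values))

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError):
            attention_rollout([np.eye(4), np.eye(5)])
        with pytest.raises(ValueError):
            attention_rollout([np.ones((3, 4))])


class TestHiResCAM:
    def test_linear_model_matches_analytic_gradient(self, rng):
        """If the score is the mean of feature channel 0, the CAM is exactly
        channel0 / N with zero contribution from other channels."""
        cfg = rt.EnsembleConfig(input_channels=1, input_shape=(16, 16, 8),
                                cnn_filters=(4,), cnn_feature_dim=8, fusion="cnn_only")
        model = EnsembleModel(cfg, seed=0)
        # head o fc: make the logit equal the global mean of channel 0
        model.cnn.fc.W.value[...] = 0.0
        model.cnn.fc.W.value[0, 0] = 1.0
        model.cnn.fc.b.value[...] = 0.0
        model.head.W.value[...] = 0.0
        model.head.W.value[0, 0] = 1.0
        model.head.b.value[...] = 0.0
        x = rng.standard_normal((1, 1, 16, 16, 8))
        amap = hirescam(model, x, class_index=1, block_index=-1)
        A = model.cnn.block_outputs[-1]
        N = np.prod(A.shape[2:])
        from radtexnet.explain import _upsample

        np.testing.assert_allclose(amap.values, _upsample(A[0, 0] / N, (16, 16, 8)),
                                   atol=1e-12)

    def test_backprop_gradient_matches_finite_differences(self, rng):
        cfg = rt.EnsembleConfig(input_channels=1, input_shape=(8, 8, 8),
                                cnn_filters=(4, 8), cnn_feature_dim=6, fusion="cnn_only")
        model = EnsembleModel(cfg, seed=3)
        x = rng.standard_normal((1, 1, 8, 8, 8))
        hirescam(model, x, class_index=1, block_index=1)
        A = model.cnn.block_outputs[1].copy()
        dA = model.cnn.block_grads[1]
        eps = 1e-6
        flat = [(0, c, i, j, k) for c in (0, 3) for i in (0, 1) for j in (1,) for k in (0, 1)]
        for idx in flat:
            Ap, Am = A.copy(), A.copy()
            Ap[idx] += eps
            Am[idx] -= eps
            sp = model.head.forward(model.cnn.forward_from(1, Ap))[0, 0]
            sm = model.head.forward(model.cnn.forward_from(1, Am))[0, 0]
            num = (sp - sm) / (2 * eps)
            rel = abs(num - dA[idx]) / max(1e-12, abs(num) + abs(dA[idx]))
            assert rel < 1e-4, (idx, num, dA[idx])

    def test_zero_feature_maps_give_zero_map(self, rng):
        cfg = rt.EnsembleConfig(input_channels=1, input_shape=(8, 8, 8),
                                cnn_filters=(4,), cnn_feature_dim=4, fusion="cnn_only")
        model = EnsembleModel(cfg, seed=0)
        for block in model.cnn.blocks:
            for layer in block.modules_list:
                if hasattr(layer, "b") and layer.b is not None:
                    layer.b.value[...] = 0.0
        amap = hirescam(model, np.zeros((1, 1, 8, 8, 8)), class_index=1)
        np.testing.assert_allclose(amap.values, 0.0, atol=1e-12)

    def test_vit_only_model_rejected(self, rng):
        cfg = rt.EnsembleConfig(input_channels=1, input_shape=(16, 16, 16),
                                vit_patch_edge=8, vit_depth=1, vit_dim=8,
                                vit_heads=2, fusion="vit_only")
        with pytest.raises(ValueError):
            hirescam(EnsembleModel(cfg, seed=0), np.zeros((1, 1, 16, 16, 16)))


class TestOverlay:
    def _map_and_volume(self, rng):
        vol = CTVolume(rng.uniform(-1000, 400, (8, 8, 4)))
        amap = rt.AttentionMap(values=rng.standard_normal((8, 8, 4)), source="hirescam")
        return amap, vol

    def test_alpha_zero_returns_ct_slice(self, rng):
        amap, vol = self._map_and_volume(rng)
        img = overlay(amap, vol, 2, alpha=0.0)
        expected = rt.minmax_normalize(vol.voxels[:, :, 2])
        np.testing.assert_allclose(img[:, :, 0], expected, atol=1e-12)
        np.testing.assert_allclose(img[:, :, 1], expected, atol=1e-12)

    def test_alpha_one_is_pure_colormap(self, rng):
        import matplotlib

        amap, vol = self._map_and_volume(rng)
        img = overlay(amap, vol, 1, alpha=1.0)
        expected = matplotlib.colormaps["jet"](amap.display()[:, :, 1])[:, :, :3]
        np.testing.assert_allclose(img, expected, atol=1e-12)

    def test_out_of_range_slice_rejected(self, rng):
        amap, vol = self._map_and_volume(rng)
        with pytest.raises(IndexError):
            overlay(amap, vol, 99)


class TestLocalization:
    def test_hirescam_peak_falls_inside_nodule(self):
        """A model whose only class evidence is a hyperintense nodule places
        its full-resolution CAM peak inside the (dilated) nodule mask in at
        least 8 of 10 held-out phantoms."""
        base = rt.PhantomSpec(shape=(32, 32, 16), kind="focal_nodule",
                              noise_sd=30.0, nodule_count=0)
        neg = dataclasses.replace(base, nodule_count=1, nodule_radius=4.0,
                                  nodule_contrast=600.0)
        vols, _, _ = rt.make_cohort(12, base, neg, seed=7)
        y = np.array([v.label for v in vols])
        X = np.stack([rt.minmax_normalize(np.clip(v.voxels, -1000, 400))
                      for v in vols])[:, None]
        cfg = rt.EnsembleConfig(input_channels=1, input_shape=(32, 32, 16),
                                cnn_filters=(8, 16, 32), cnn_feature_dim=32,
                                fusion="cnn_only")
        model, _ = rt.train_model(X, y, cfg, rt.desk_scale_train_spec(seed=0, epochs=8))
        hits = 0
        for s in range(100, 110):
            vol, mask = rt.make_phantom(dataclasses.replace(neg, seed=s))
            x = rt.minmax_normalize(np.clip(vol.voxels, -1000, 400))[None]
            amap = hirescam(model, x, class_index=0, block_index=0)
            peak = np.unravel_index(np.argmax(amap.values), amap.values.shape)
            hits += bool(ndimage.binary_dilation(mask, iterations=3)[peak])
        assert hits >= 8
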