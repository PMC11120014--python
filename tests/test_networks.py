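import numpy as np
import pytest

import radtexnet as rt
from radtexnet.networks import CNNBranch, ViTBranch, EnsembleModel
from radtexnet.nn import bce_loss


class TestConfig:
    def test_default_config_reproduces_published_architecture(self):
        cfg = rt.EnsembleConfig()
        assert cfg.cnn_filters == (16, 32, 64, 128, 256, 512)
        assert cfg.cnn_first_kernel == 3 and cfg.cnn_down_kernel == 4
        assert cfg.cnn_feature_dim == 768 and cfg.vit_dim == 768
        assert cfg.vit_depth == 12 and cfg.vit_heads == 6 and cfg.vit_patch_edge == 16
        # shape audit: six stride-2 blocks halve 256x256x64 down to 4x4x1
        assert cfg.conv_shape_chain()[-1] == (4, 4, 1)
        assert cfg.n_tokens() == 1 + 16 * 16 * 4  # 1025 tokens incl. class token
        assert cfg.fusion_width() == 1536

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            rt.EnsembleConfig(input_shape=(250, 256, 64))  # not divisible by patch
        with pytest.raises(ValueError):
            rt.EnsembleConfig(vit_dim=100, vit_heads=6)
        with pytest.raises(ValueError):
            rt.EnsembleConfig(cnn_filters=(64, 32))
        with pytest.raises(ValueError):
            rt.EnsembleConfig(input_shape=(24, 24, 24), fusion="cnn_only",
                              vit_patch_edge=8)  # 24 not divisible through 6 halvings


class TestCNNBranch:
    def test_reduced_shape_chain_matches_conv_arithmetic(self, rng):
        cfg = rt.EnsembleConfig(input_channels=1, input_shape=(32, 32, 16),
                                cnn_filters=(4, 8), cnn_feature_dim=16,
                                fusion="cnn_only")
        assert cfg.conv_shape_chain() == [(32, 32, 16), (16, 16, 8), (8, 8, 4)]
        branch = CNNBranch(cfg, rng)
        out = branch.forward(rng.standard_normal((2, 1, 32, 32, 16)))
        assert out.shape == (2, 16)
        spatial = [b.shape[2:] for b in branch.block_outputs]
        assert spatial == [(32, 32, 16), (16, 16, 8), (8, 8, 4)]

    def test_zero_input_bias_free_gives_zero_prepool_activations(self, rng):
        cfg = rt.EnsembleConfig(input_channels=1, input_shape=(16, 16, 8),
                                cnn_filters=(4,), cnn_feature_dim=8, fusion="cnn_only")
        branch = CNNBranch(cfg, rng)
        for block in branch.blocks:
            for layer in block.modules_list:
                if hasattr(layer, "b") and layer.b is not None:
                    layer.b.value[...] = 0.0
        branch.forward(np.zeros((1, 1, 16, 16, 8)))
        # conv(0) = 0, ReLU(0) = 0, BN(0) with zero shift = 0
        np.testing.assert_allclose(branch.block_outputs[-1], 0.0, atol=1e-12)


class TestViTBranch:
    def test_token_count_and_attention_shapes(self, tiny_cfg, rng):
        branch = ViTBranch(tiny_cfg, rng)
        out = branch.forward(rng.standard_normal((2, 2, 16, 16, 8)))
        assert out.shape == (2, 16)
        atts = branch.attentions()
        assert len(atts) == tiny_cfg.vit_depth
        T = tiny_cfg.n_tokens()
        assert atts[0].shape == (2, tiny_cfg.vit_heads, T, T)

    def test_attention_rows_sum_to_one(self, tiny_cfg, rng):
        branch = ViTBranch(tiny_cfg, rng)
        branch.forward(rng.standard_normal((1, 2, 16, 16, 8)))
        for att in branch.attentions():
            np.testing.assert_allclose(att.sum(axis=-1), 1.0, atol=1e-6)

    def test_patch_permutation_with_position_embeddings_is_equivariant(self, rng):
        """Permuting patches together with their position embeddings leaves
        the class-token output unchanged."""
        cfg = rt.EnsembleConfig(input_channels=1, input_shape=(16, 16, 8),
                                cnn_filters=(4,), cnn_feature_dim=8,
                                vit_patch_edge=8, vit_depth=2, vit_dim=12,
                                vit_heads=3, fusion="vit_only")
        branch = ViTBranch(cfg, rng)
        x = rng.standard_normal((1, 1, 16, 16, 8))
        out1 = branch.forward(x).copy()

        tokens = branch.patchify(x)
        perm = rng.permutation(tokens.shape[1])
        # permute both the patch tokens (via a permuted input reconstruction)
        # and the corresponding position embeddings
        branch.pos.value[:, 1:] = branch.pos.value[:, 1:][:, perm]
        x_perm = branch.unpatchify_grad(tokens[:, perm], x.shape)
        out2 = branch.forward(x_perm)
        np.testing.assert_allclose(out1, out2, atol=1e-10)


class TestEnsemble:
    def test_probability_strictly_inside_unit_interval(self, tiny_cfg, rng):
        model = EnsembleModel(tiny_cfg, seed=0)
        p = model.forward(rng.standard_normal((3, 2, 16, 16, 8)))
        assert np.all(p > 0) and np.all(p < 1)

    def test_concat_fusion_width_is_sum_of_branch_dims(self, tiny_cfg):
        model = EnsembleModel(tiny_cfg, seed=0)
        assert model.head.W.value.shape == (1, tiny_cfg.cnn_feature_dim + tiny_cfg.vit_dim)

    @pytest.mark.parametrize("fusion,channels", [
        ("concat", 2), ("cnn_only", 1), ("vit_only", 1),
    ])
    def test_single_and_dual_branch_variants_run(self, fusion, channels, rng):
        cfg = rt.EnsembleConfig(input_channels=channels, input_shape=(16, 16, 8),
                                cnn_filters=(4, 8), cnn_feature_dim=12,
                                vit_patch_edge=8, vit_depth=1, vit_dim=12,
                                vit_heads=3, fusion=fusion)
        model = EnsembleModel(cfg, seed=1)
        p = model.forward(rng.standard_normal((2, channels, 16, 16, 8)))
        assert p.shape == (2,)

    def test_forward_deterministic_in_eval_mode(self, tiny_cfg, rng):
        model = EnsembleModel(tiny_cfg, seed=5)
        x = rng.standard_normal((2, 2, 16, 16, 8))
        np.testing.assert_array_equal(model.forward(x), model.forward(x))

    def test_backprop_matches_finite_differences(self, rng):
        """End-to-end gradient check through conv, BN, attention and fusion."""
        cfg = rt.EnsembleConfig(input_channels=2, input_shape=(16, 16, 8),
                                cnn_filters=(4, 8), cnn_feature_dim=10,
                                vit_patch_edge=8, vit_depth=1, vit_dim=12,
                                vit_heads=3, fusion="concat")
        model = EnsembleModel(cfg, seed=2)
        X = rng.standard_normal((3, 2, 16, 16, 8))
        y = np.array([1.0, 0.0, 1.0])
        loss, dl = bce_loss(model.logits(X, train=True), y)
        model.zero_grad()
        model.backward(dl)
        eps = 1e-6
        for p in model.parameters()[::7]:  # sample parameter tensors
            idx = np.unravel_index(p.value.size // 2, p.value.shape)
            orig = p.value[idx]
            p.value[idx] = orig + eps
            lp, _ = bce_loss(model.logits(X, train=True), y)
            p.value[idx] = orig - eps
            lm, _ = bce_loss(model.logits(X, train=True), y)
            p.value[idx] = orig
            num = (lp - lm) / (2 * eps)
            rel = abs(num - p.grad[idx]) / max(1e-10, abs(num) + abs(p.grad[idx]))
            assert rel < 1e-5, (p.name, num, p.grad[idx])
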