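import numpy as np
import pytest

import radtexnet as rt


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cfg():
    """A minimal two-channel ensemble configuration for fast tests."""
    return rt.EnsembleConfig(
        input_channels=2, input_shape=(16, 16, 8), cnn_filters=(8, 16),
        cnn_feature_dim=24, vit_patch_edge=8, vit_depth=2, vit_dim=16,
        vit_heads=4, fusion="concat",
    )


@pytest.fixture(scope="session")
def desk_cfg():
    """The reduced two-channel ensemble used by the desk-scale harness."""
    return rt.EnsembleConfig(
        input_channels=2, input_shape=(32, 32, 16), cnn_filters=(8, 16, 32),
        cnn_feature_dim=64, vit_patch_edge=8, vit_depth=2, vit_dim=64,
        vit_heads=4, fusion="concat",
    )


@pytest.fixture(scope="session")
def desk_texture_spec():
    return rt.TextureSpec(gray_levels=8, quant_range=(-1000.0, 400.0))


@pytest.fixture(scope="session")
def easy_cohort(desk_texture_spec):
    """30/class easy-regime phantoms with CT + HaralickCorrelation channels.

    Session-scoped: this cohort feeds both the end-to-end harness checks and
    the generator separability checks, and texture maps are the slow part.
    """
    pos, neg = rt.default_class_specs((32, 32, 16), "easy")
    vols, masks, manifest = rt.make_cohort(30, pos, neg, seed=1)
    y = np.array([v.label for v in vols])
    maps = [rt.texture_maps(v, desk_texture_spec) for v in vols]
    ct = np.stack([rt.minmax_normalize(np.clip(v.voxels, -1000, 400)) for v in vols])
    rad = np.stack([rt.minmax_normalize(m.maps["HaralickCorrelation"]) for m in maps])
    return {"volumes": vols, "masks": masks, "manifest": manifest, "labels": y,
            "map_sets": maps, "ct": ct, "rad": rad}
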