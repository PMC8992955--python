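import numpy as np
import pytest

from adaunet import (
    DiscriminatorConfig,
    SegmentorConfig,
    attention_block,
    attention_map,
    build_discriminator,
    build_segmentor,
    load_checkpoint,
    n_parameters,
    save_checkpoint,
)


def attention_oracle(feats, delta):
    """Explicit double-loop evaluation of the attention block (identity proj).

    Affinity of position m to n is the channel dot product; rows are
    softmax-normalized; output at m is delta * sum_n A[m,n] * I_n + I_m.
    """
    c, h, w = feats.shape
    n = h * w
    cols = feats.reshape(c, n)
    attn = np.zeros((n, n))
    for m in range(n):
        e = np.array([np.exp(cols[:, nn] @ cols[:, m]) for nn in range(n)])
        attn[m] = e / e.sum()
    out = np.zeros_like(cols)
    for m in range(n):
        agg = np.zeros(c)
        for nn in range(n):
            agg += attn[m, nn] * cols[:, nn]
        out[:, m] = delta * agg + cols[:, m]
    return out.reshape(c, h, w), attn


class TestAttentionBlock:
    def test_delta_zero_is_identity(self, rng):
        x = rng.normal(size=(5, 4, 4))
        np.testing.assert_array_equal(attention_block(x, 0.0), x)

    def test_constant_features_give_uniform_rows(self):
        x = np.ones((3, 2, 3)) * 1.7
        attn = attention_map(x)
        np.testing.assert_allclose(attn, 1.0 / 6, atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        attn = attention_map(rng.normal(size=(4, 3, 3)) * 3)
        np.testing.assert_allclose(attn.sum(axis=1), 1.0, atol=1e-5)
        assert (attn >= 0).all()

    @pytest.mark.parametrize("shape", [(3, 2, 2), (8, 4, 4), (1, 2, 3)])
    def test_matches_loop_oracle(self, rng, shape):
        x = rng.normal(size=shape)
        delta = float(rng.uniform(-1, 1))
        expected, attn_expected = attention_oracle(x, delta)
        np.testing.assert_allclose(attention_block(x, delta), expected, atol=1e-5)
        np.testing.assert_allclose(attention_map(x), attn_expected, atol=1e-5)

    def test_permutation_covariance(self, rng):
        x = rng.normal(size=(3, 2, 4))
        c, h, w = x.shape
        perm = rng.permutation(h * w)
        xp = x.reshape(c, -1)[:, perm].reshape(c, h, w)
        out = attention_block(x, 0.8).reshape(c, -1)
        outp = attention_block(xp, 0.8).reshape(c, -1)
        np.testing.assert_allclose(outp, out[:, perm], atol=1e-10)

    def test_nonfinite_rejected(self):
        bad = np.full((2, 2, 2), np.nan)
        with pytest.raises(ValueError, match="finite"):
            attention_block(bad, 0.5)


VARIANT_TABLE = {
    "unet": (0, 0), "au_net": (0, 1), "dau_net": (0, 2),
    "adau_a1": (1, 2), "adau_a2": (2, 2), "adau_a3": (3, 2),
}


class TestSegmentorZoo:
    @pytest.mark.parametrize("variant,expected", VARIANT_TABLE.items())
    def test_attention_and_head_counts(self, variant, expected):
        cfg = SegmentorConfig(variant=variant, base_channels=4, depth=3)
        model = build_segmentor(cfg)
        assert len(model.attention_blocks) == expected[0]
        assert cfg.n_heads == expected[1]
        assert (model.aux_head is not None) == (expected[1] == 2)

    def test_invalid_variant(self):
        with pytest.raises(ValueError, match="variant"):
            SegmentorConfig(variant="vnet")

    def test_build_determinism(self):
        cfg = SegmentorConfig(variant="adau_a1", base_channels=4, depth=2)
        a, b = build_segmentor(cfg, seed=5), build_segmentor(cfg, seed=5)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)
        c = build_segmentor(cfg, seed=6)
        assert any(
            not np.array_equal(pa.data, pc.data)
            for pa, pc in zip(a.parameters(), c.parameters())
        )

    def test_param_count_function_of_config(self):
        cfg = SegmentorConfig(variant="dau_net", base_channels=4, depth=2)
        assert n_parameters(build_segmentor(cfg, seed=0)) == \
            n_parameters(build_segmentor(cfg, seed=99))

    def test_forward_probability_range_all_variants(self, rng):
        img = rng.random((16, 16)).astype(np.float32)
        for variant in VARIANT_TABLE:
            model = build_segmentor(
                SegmentorConfig(variant=variant, base_channels=4, depth=2))
            out = model.predict(img)
            assert out.main_map.shape == (16, 16)
            assert out.main_map.min() >= 0 and out.main_map.max() <= 1
            if VARIANT_TABLE[variant][1] == 2:
                assert out.aux_map.shape == (8, 8)
                assert out.aux_map.min() >= 0 and out.aux_map.max() <= 1
            else:
                assert out.aux_map is None

    def test_aux_map_half_resolution_208(self):
        model = build_segmentor(SegmentorConfig(variant="dau_net", base_channels=4))
        out = model.predict(np.zeros((208, 208), dtype=np.float32))
        assert out.main_map.shape == (208, 208)
        assert out.aux_map.shape == (104, 104)

    def test_indivisible_size_error_names_multiple(self):
        model = build_segmentor(SegmentorConfig(variant="unet", base_channels=4))
        with pytest.raises(ValueError, match="16"):
            model.predict(np.zeros((50, 50), dtype=np.float32))

    def test_zero_weight_head_gives_half(self):
        model = build_segmentor(SegmentorConfig(variant="unet", base_channels=4, depth=2))
        model.head.w.data[:] = 0
        model.head.b.data[:] = 0
        out = model.predict(np.random.default_rng(0).random((16, 16)))
        np.testing.assert_allclose(out.main_map, 0.5, atol=1e-7)

    def test_eval_determinism(self, rng):
        model = build_segmentor(SegmentorConfig(variant="adau_a2", base_channels=4, depth=2))
        img = rng.random((16, 16)).astype(np.float32)
        a, b = model.predict(img), model.predict(img)
        np.testing.assert_array_equal(a.main_map, b.main_map)
        np.testing.assert_array_equal(a.aux_map, b.aux_map)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        cfg = SegmentorConfig(variant="adau_a1", base_channels=4, depth=2)
        model = build_segmentor(cfg, seed=3)
        save_checkpoint(model, tmp_path / "model.npz")
        loaded = load_checkpoint(tmp_path / "model.npz")
        assert loaded.config == cfg
        img = rng.random((16, 16)).astype(np.float32)
        np.testing.assert_array_equal(
            loaded.predict(img).main_map, model.predict(img).main_map)


class TestDiscriminator:
    def test_default_has_five_layers_with_stated_kernels(self):
        d = build_discriminator()
        assert d.n_conv_layers == 5
        kernels = tuple(
            (l.conv.w.data.shape[-1] if hasattr(l, "conv") else l.w.data.shape[-1])
            for l in d.layers
        )
        assert kernels == (4, 4, 4, 5, 7)

    def test_output_scalar_probability(self, rng):
        d = build_discriminator(DiscriminatorConfig(channels=(4, 8, 8, 8, 1)))
        p = d.predict(rng.random((64, 64)).astype(np.float32))
        assert 0.0 <= p <= 1.0

    def test_config_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            DiscriminatorConfig(kernel_sizes=(4, 4), channels=(8, 8, 1), strides=(2, 2))
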