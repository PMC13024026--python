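import numpy as np
import pytest

from brainage import (BackboneConfig, FusionConfig, ViTConfig, build_model,
                      build_baseline, axis_split, sinusoidal_pe_3d, token_prune)
from brainage.fusion import (PatchEmbed3d, SelfAttentionBlock, CrossAttentionBlock,
                             RegressionHead, inspect_shapes, ResNetCrossViT)
from brainage.nn import Tensor, manual_seed

RNG = np.random.default_rng(11)


def tensor(*shape):
    return Tensor(RNG.standard_normal(shape).astype(np.float32))


# ---------------------------------------------------------------------------
# axis split and positional encoding
# ---------------------------------------------------------------------------

class TestAxisSplit:
    @pytest.mark.parametrize("dim,expected", [
        (96, (32, 32, 32)), (160, (54, 54, 52)), (6, (2, 2, 2))])
    def test_reference_splits(self, dim, expected):
        assert axis_split(dim) == expected

    def test_property_sweep_even_dims(self):
        for dim in range(6, 514, 2):
            dz, dy, dx = axis_split(dim)
            assert dz == dy
            assert dz % 2 == 0 and dx % 2 == 0
            assert dz + dy + dx == dim
            assert abs(dz - dx) <= 2

    def test_rejects_small_or_odd(self):
        with pytest.raises(ValueError):
            axis_split(4)
        with pytest.raises(ValueError):
            axis_split(97)


class TestSinusoidalPE:
    def test_range_and_origin(self):
        pe = sinusoidal_pe_3d((4, 5, 4), 96)
        assert pe.shape == (80, 96)
        assert np.all(pe >= -1) and np.all(pe <= 1)
        origin = pe[0]  # coordinate (0, 0, 0): sines 0, cosines 1
        np.testing.assert_allclose(origin[0::2], 0.0, atol=1e-7)
        np.testing.assert_allclose(origin[1::2], 1.0, atol=1e-7)

    @pytest.mark.parametrize("grid", [(3, 3, 3), (6, 6, 6), (2, 5, 4)])
    def test_positions_pairwise_distinct(self, grid):
        pe = sinusoidal_pe_3d(grid, 96)
        n = pe.shape[0]
        dists = np.linalg.norm(pe[:, None] - pe[None, :], axis=-1)
        assert np.all(dists[~np.eye(n, dtype=bool)] > 1e-6)


# ---------------------------------------------------------------------------
# tokenization
# ---------------------------------------------------------------------------

class TestPatchEmbed:
    def test_token_counts_on_stage_features(self):
        manual_seed(1)
        large = PatchEmbed3d(128, 160)
        assert large(tensor(1, 128, 11, 13, 11)).data.shape == (1, 150, 160)
        small = PatchEmbed3d(256, 96)
        assert small(tensor(1, 256, 6, 7, 6)).data.shape == (1, 27, 96)

    def test_single_patch_and_too_small(self):
        manual_seed(2)
        pe = PatchEmbed3d(4, 8)
        assert pe(tensor(1, 4, 2, 2, 2)).data.shape == (1, 1, 8)
        with pytest.raises(ValueError, match="patch"):
            pe(tensor(1, 4, 1, 2, 2))


class TestTokenPrune:
    def test_keep_rate_one_and_eval_are_identity(self):
        t = tensor(2, 11, 8)
        rng = np.random.default_rng(0)
        assert token_prune(t, 1.0, rng, training=True) is t
        assert token_prune(t, 0.3, rng, training=False) is t

    def test_half_rate_keeps_ceil_and_cls(self):
        t = tensor(1, 151, 8)  # cls + 150 patches
        out = token_prune(t, 0.5, np.random.default_rng(3), training=True)
        assert out.data.shape == (1, 76, 8)  # ceil(75.0) + cls
        np.testing.assert_array_equal(out.data[:, 0], t.data[:, 0])


# ---------------------------------------------------------------------------
# attention blocks
# ---------------------------------------------------------------------------

class TestSelfAttention:
    def test_head_and_mlp_dimensions(self):
        manual_seed(3)
        small = SelfAttentionBlock(96, heads=4)
        large = SelfAttentionBlock(160, heads=4)
        assert small.attn.dh == 24 and large.attn.dh == 40
        assert small.mlp.fc1.weight.data.shape == (96, 384)
        assert large.mlp.fc1.weight.data.shape == (160, 640)

    def test_zero_layerscale_is_identity_in_eval(self):
        manual_seed(4)
        blk = SelfAttentionBlock(24, heads=4)
        blk.ls1.gamma.data[:] = 0
        blk.ls2.gamma.data[:] = 0
        blk.eval()
        x = tensor(2, 9, 24)
        np.testing.assert_array_equal(blk(x).data, x.data)


class TestCrossAttention:
    def test_fresh_gates_and_dims_preserved(self):
        manual_seed(5)
        cross = CrossAttentionBlock(96, 160)
        assert cross.gate_s.data[0] == pytest.approx(0.1)
        assert cross.gate_l.data[0] == pytest.approx(0.1)
        cross.eval()
        s, l = cross(tensor(2, 28, 96), tensor(2, 151, 160))
        assert s.data.shape == (2, 28, 96) and l.data.shape == (2, 151, 160)

    def test_zero_gates_leave_cls_unchanged(self):
        manual_seed(6)
        cross = CrossAttentionBlock(24, 40)
        cross.gate_s.data[:] = 0
        cross.gate_l.data[:] = 0
        cross.eval()
        small, large = tensor(2, 5, 24), tensor(2, 7, 40)
        s2, l2 = cross(small, large)
        np.testing.assert_array_equal(s2.data, small.data)
        np.testing.assert_array_equal(l2.data, large.data)

    def test_missing_cls_rejected(self):
        manual_seed(7)
        cross = CrossAttentionBlock(24, 40)
        with pytest.raises(ValueError, match="cls"):
            cross(tensor(1, 1, 24), tensor(1, 1, 40))


class TestRegressionHead:
    def test_widths(self):
        manual_seed(8)
        head = RegressionHead()
        assert head.fc1.weight.data.shape == (256, 192)
        assert head.fc2.weight.data.shape == (192, 1)

    def test_zero_weights_yield_bias(self):
        manual_seed(9)
        head = RegressionHead(24, 40, hidden=16)
        head.eval()
        head.fc2.weight.data[:] = 0
        head.fc2.bias.data[:] = 7.25
        out = head(tensor(3, 1, 24), tensor(3, 1, 40))
        np.testing.assert_allclose(out.data, 7.25, atol=1e-6)


# ---------------------------------------------------------------------------
# assembled models
# ---------------------------------------------------------------------------

class TestFullModel:
    def test_scalar_output_and_eval_determinism(self, tiny_backbone_cfg,
                                                tiny_fusion_cfg):
        m = build_model(tiny_backbone_cfg, tiny_fusion_cfg, seed=0)
        m.eval()
        x = tensor(2, 1, 20, 24, 20)
        y1, y2 = m(x), m(x)
        assert y1.data.shape == (2,)
        np.testing.assert_array_equal(y1.data, y2.data)

    def test_token_counts_for_standard_input(self):
        info = inspect_shapes((84, 102, 84))
        assert info["small_stream"]["patches"] == 27
        assert info["large_stream"]["patches"] == 150
        assert info["stage_shapes"]["stage2"] == (128, 11, 13, 11)
        assert info["stage_shapes"]["stage3"] == (256, 6, 7, 6)

    def test_parameter_count_stable_across_constructions(self, tiny_backbone_cfg,
                                                         tiny_fusion_cfg):
        a = build_model(tiny_backbone_cfg, tiny_fusion_cfg, seed=0)
        b = build_model(tiny_backbone_cfg, tiny_fusion_cfg, seed=99)
        assert a.num_parameters() == b.num_parameters()

    def test_config_consistency_checked_at_construction(self):
        with pytest.raises(ValueError, match="heads"):
            FusionConfig(small_embed_dim=90)  # not divisible by 4 heads
        with pytest.raises(ValueError, match="token_keep_rate"):
            FusionConfig(token_keep_rate=0.0)

    def test_zero_cross_gates_decouple_streams(self, tiny_backbone_cfg,
                                               tiny_fusion_cfg):
        """With both cross gates at 0 the prediction equals running the two
        self-attention streams independently (no cross-scale exchange)."""
        m = build_model(tiny_backbone_cfg, tiny_fusion_cfg, seed=1)
        for i in range(m.fusion_cfg.depth):
            layer = getattr(m, f"layer{i}")
            layer.cross.gate_s.data[:] = 0
            layer.cross.gate_l.data[:] = 0
        m.eval()
        x = tensor(1, 1, 20, 24, 20)
        full = m(x).data
        # manual no-cross forward with the same weights
        fm = m.backbone(x)
        small = m._tokens(fm.stage3, m.embed_small, m.cls_small)
        large = m._tokens(fm.stage2, m.embed_large, m.cls_large)
        for i in range(m.fusion_cfg.depth):
            layer = getattr(m, f"layer{i}")
            small = layer.sa_small(small)
            large = layer.sa_large(large)
        manual = m.head(small[:, 0:1], large[:, 0:1]).data.reshape(-1)
        np.testing.assert_allclose(full, manual, atol=1e-6)


class TestBaselines:
    def test_vit_only_tokenizer_and_depth(self):
        vit = build_baseline("vit_only", seed=0)
        assert vit.cfg.depth == 12
        grid = vit.embed.token_grid((84, 102, 84))
        assert int(np.prod(grid)) == 150
        assert inspect_shapes((84, 102, 84))["vit_only_patches"] == 150

    def test_all_model_kinds_emit_one_scalar(self, tiny_backbone_cfg,
                                             tiny_fusion_cfg):
        x = tensor(2, 1, 32, 32, 32)
        vit_cfg = ViTConfig(embed_dim=48, depth=2, heads=6)
        models = [
            build_model(tiny_backbone_cfg, tiny_fusion_cfg, seed=0),
            build_baseline("resnet_only", tiny_backbone_cfg, seed=0),
            build_baseline("vit_only", vit_cfg=vit_cfg, seed=0),
            build_baseline("resnet_vit_concat", tiny_backbone_cfg, vit_cfg, seed=0),
        ]
        for m in models:
            m.eval()
            assert m(x).data.shape == (2,)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            build_baseline("alexnet")


def test_checkpoint_roundtrip(tmp_path, tiny_backbone_cfg, tiny_fusion_cfg):
    from brainage.nn import save_checkpoint, load_checkpoint
    m = build_model(tiny_backbone_cfg, tiny_fusion_cfg, seed=5)
    m.eval()
    x = tensor(1, 1, 20, 24, 20)
    ref = m(x).data.copy()
    save_checkpoint(tmp_path / "ck.npz", m, config=tiny_fusion_cfg)
    m2 = build_model(tiny_backbone_cfg, tiny_fusion_cfg, seed=6)
    load_checkpoint(tmp_path / "ck.npz", m2)
    m2.eval()
    np.testing.assert_array_equal(m2(x).data, ref)
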