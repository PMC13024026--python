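import numpy as np
import pytest
from scipy import ndimage

from brainage import BackboneConfig, CoTResNet3D, backbone_stage_shapes
from brainage.backbone import (CoT3d, SE3d, ResidualBlock3d, se_hidden_width,
                               cot_hidden_width)
from brainage.nn import Tensor, functional as F, manual_seed

RNG = np.random.default_rng(7)


def tensor(*shape):
    return Tensor(RNG.standard_normal(shape).astype(np.float32))


# ---------------------------------------------------------------------------
# stem and stage arithmetic
# ---------------------------------------------------------------------------

def test_stem_shape_on_standard_and_test_grids():
    manual_seed(0)
    bb = CoTResNet3D(BackboneConfig())
    bb.eval()
    h = F.max_pool3d(bb.stem_bn(bb.stem_conv(tensor(1, 1, 84, 102, 84))).relu(), 3, 2, 1)
    assert h.data.shape == (1, 64, 21, 26, 21)
    h2 = F.max_pool3d(bb.stem_bn(bb.stem_conv(tensor(1, 1, 28, 34, 28))).relu(), 3, 2, 1)
    assert h2.data.shape == (1, 64, 7, 9, 7)


def test_stem_is_linear_before_batchnorm():
    manual_seed(0)
    bb = CoTResNet3D(BackboneConfig())
    out = bb.stem_conv(Tensor(np.zeros((1, 1, 16, 16, 16), np.float32)))
    np.testing.assert_array_equal(out.data, 0.0)


def test_stage_shapes_arithmetic_on_standard_input():
    trace = backbone_stage_shapes((84, 102, 84))
    assert trace["stage1"] == (21, 26, 21)
    assert trace["stage2"] == (11, 13, 11)
    assert trace["stage3"] == (6, 7, 6)
    # total stride from input to stage 3 is 16 along each axis
    big = backbone_stage_shapes((160, 160, 160))
    assert big["stage3"] == (10, 10, 10)


def test_shape_inference_matches_execution_for_random_sizes(tiny_backbone_cfg):
    manual_seed(1)
    bb = CoTResNet3D(tiny_backbone_cfg)
    bb.eval()
    rng = np.random.default_rng(5)
    for _ in range(30):
        shape = tuple(int(v) for v in rng.integers(16, 40, 3))
        fm = bb(tensor(1, 1, *shape))
        trace = backbone_stage_shapes(shape)
        assert fm.stage1.data.shape[2:] == trace["stage1"]
        assert fm.stage2.data.shape[2:] == trace["stage2"]
        assert fm.stage3.data.shape[2:] == trace["stage3"]


# ---------------------------------------------------------------------------
# CoT module
# ---------------------------------------------------------------------------

def oracle_avg_pool(x, f=2):
    B, C, D, H, W = x.shape
    out = np.zeros((B, C, -(-D // f), -(-H // f), -(-W // f)))
    for z in range(out.shape[2]):
        for y in range(out.shape[3]):
            for xx in range(out.shape[4]):
                blk = x[:, :, z * f:(z + 1) * f, y * f:(y + 1) * f, xx * f:(xx + 1) * f]
                out[:, :, z, y, xx] = blk.mean(axis=(2, 3, 4))
    return out


def oracle_weighted_unfold(values, weights):
    """Triple-loop 3x3x3 weighted aggregation with zero padding."""
    B, C, D, H, W = values.shape
    vp = np.pad(values, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
    out = np.zeros_like(values)
    for idx, (a, b, c) in enumerate(np.ndindex(3, 3, 3)):
        out += weights[:, None, idx] * vp[:, :, a:a + D, b:b + H, c:c + W]
    return out


def oracle_trilinear(x, out_shape):
    """Half-pixel-center trilinear resize via scipy map_coordinates."""
    B, C = x.shape[:2]
    src = x.shape[2:]
    grids = [np.clip((np.arange(n) + 0.5) * s / n - 0.5, 0, s - 1)
             for n, s in zip(out_shape, src)]
    coords = np.meshgrid(*grids, indexing="ij")
    out = np.empty((B, C, *out_shape))
    for b in range(B):
        for c in range(C):
            out[b, c] = ndimage.map_coordinates(x[b, c], coords, order=1,
                                                mode="nearest")
    return out


@pytest.mark.parametrize("shape", [(1, 8, 4, 4, 4), (2, 8, 6, 6, 6), (1, 8, 5, 6, 5)])
def test_cot_aggregate_matches_bruteforce_oracle(shape):
    manual_seed(3)
    cot = CoT3d(shape[1], groups=4)
    cot.eval()
    x = RNG.standard_normal(shape).astype(np.float32)
    pooled_grid = tuple(-(-n // 2) for n in shape[2:])
    w = RNG.random((shape[0], 27, *pooled_grid)).astype(np.float32)
    w /= w.sum(axis=1, keepdims=True)
    got = cot.aggregate(Tensor(x), Tensor(w)).data
    pooled = oracle_avg_pool(x.astype(np.float64))
    agg = oracle_weighted_unfold(pooled, w.astype(np.float64))
    resized = oracle_trilinear(agg, shape[2:])
    pw = cot.proj.weight.data.reshape(shape[1], shape[1]).astype(np.float64)
    expected = np.einsum("oc,bcdhw->bodhw", pw, resized) + \
        cot.proj.bias.data.reshape(1, -1, 1, 1, 1)
    np.testing.assert_allclose(got, expected, atol=1e-5)


def test_cot_uniform_weights_give_box_mean():
    manual_seed(4)
    cot = CoT3d(8, groups=4)
    cot.proj.weight.data = np.eye(8, dtype=np.float32).reshape(8, 8, 1, 1, 1)
    cot.proj.bias.data[:] = 0
    x = RNG.standard_normal((1, 8, 4, 4, 4)).astype(np.float32)
    w = np.full((1, 27, 2, 2, 2), 1 / 27, np.float32)
    got = cot.aggregate(Tensor(x), Tensor(w)).data
    pooled = oracle_avg_pool(x.astype(np.float64))
    box = oracle_weighted_unfold(pooled, np.full((1, 27, 2, 2, 2), 1 / 27))
    np.testing.assert_allclose(got, oracle_trilinear(box, (4, 4, 4)), atol=1e-5)


def test_cot_one_hot_center_weight_is_identity_on_pooled_field():
    manual_seed(4)
    cot = CoT3d(8, groups=4)
    cot.proj.weight.data = np.eye(8, dtype=np.float32).reshape(8, 8, 1, 1, 1)
    cot.proj.bias.data[:] = 0
    x = RNG.standard_normal((1, 8, 4, 4, 4)).astype(np.float32)
    w = np.zeros((1, 27, 2, 2, 2), np.float32)
    w[:, 13] = 1.0  # center of the 3x3x3 neighborhood
    got = cot.aggregate(Tensor(x), Tensor(w)).data
    expected = oracle_trilinear(oracle_avg_pool(x.astype(np.float64)), (4, 4, 4))
    np.testing.assert_allclose(got, expected, atol=1e-5)


def test_cot_context_weights_are_a_27_simplex():
    manual_seed(5)
    cot = CoT3d(16, groups=4)
    cot.eval()
    w = cot.context_weights(tensor(2, 16, 6, 6, 6), value_grid=(3, 3, 3)).data
    assert w.shape == (2, 27, 3, 3, 3)
    np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-6)
    assert np.all(w >= 0)


def test_cot_hidden_width_and_gate_init():
    assert cot_hidden_width(128) == 16
    assert cot_hidden_width(4) == 1
    cot = CoT3d(128, groups=4)
    assert cot.hidden == 16
    assert cot.gate.data[0] == pytest.approx(0.5)
    assert cot.reduce.weight.data.shape[1] == 256  # concat doubles the channels


def test_cot_gate_zero_is_identity_and_shape_preserved():
    manual_seed(6)
    cot = CoT3d(8, groups=4)
    cot.eval()
    x = tensor(1, 8, 5, 6, 5)
    cot.gate.data[:] = 0.0
    np.testing.assert_array_equal(cot(x).data, x.data)
    cot.gate.data[:] = 0.5
    assert cot(x).data.shape == x.data.shape


def test_cot_rejects_indivisible_groups():
    with pytest.raises(ValueError, match="groups"):
        CoT3d(10, groups=4)


# ---------------------------------------------------------------------------
# SE3D module
# ---------------------------------------------------------------------------

def test_se_hidden_widths():
    assert se_hidden_width(128) == 32
    assert se_hidden_width(256) == 64
    assert se_hidden_width(64) == 16
    assert se_hidden_width(16) == 8   # floored at 8


def test_se_zeroed_excitation_halves_input():
    manual_seed(7)
    se = SE3d(8)
    for p in (se.fc1.weight, se.fc1.bias, se.fc2.weight, se.fc2.bias):
        p.data[:] = 0
    x = tensor(2, 8, 3, 3, 3)
    np.testing.assert_allclose(se(x).data, x.data / 2, atol=1e-7)


def test_se_gates_strictly_inside_unit_interval():
    manual_seed(8)
    se = SE3d(8)
    x = tensor(2, 8, 3, 3, 3)
    s = x.mean(axis=(2, 3, 4), keepdims=True)
    gate = se.fc2(se.fc1(s).relu()).sigmoid().data
    assert np.all(gate > 0) and np.all(gate < 1)


# ---------------------------------------------------------------------------
# residual blocks and full backbone
# ---------------------------------------------------------------------------

def test_stage_transition_blocks_match_printed_shapes():
    manual_seed(9)
    cfg = BackboneConfig()
    blk2 = ResidualBlock3d(64, 128, stride=2, cfg=cfg, use_cot=True)
    blk2.eval()
    assert blk2(tensor(1, 64, 21, 26, 21)).data.shape == (1, 128, 11, 13, 11)
    blk3 = ResidualBlock3d(128, 256, stride=2, cfg=cfg, use_cot=True)
    blk3.eval()
    assert blk3(tensor(1, 128, 11, 13, 11)).data.shape == (1, 256, 6, 7, 6)
    blk1 = ResidualBlock3d(64, 64, stride=1, cfg=cfg, use_cot=False)
    blk1.eval()
    assert blk1.cot is None
    assert blk1(tensor(1, 64, 10, 12, 10)).data.shape == (1, 64, 10, 12, 10)


def test_backbone_forward_contract(tiny_backbone_cfg):
    manual_seed(10)
    bb = CoTResNet3D(tiny_backbone_cfg)
    bb.eval()
    x = tensor(2, 1, 28, 34, 28)
    fm = bb(x)
    assert fm.stage1.data.shape == (2, 16, 7, 9, 7)
    assert fm.stage2.data.shape == (2, 32, 4, 5, 4)
    assert fm.stage3.data.shape == (2, 64, 2, 3, 2)
    np.testing.assert_array_equal(bb(x).stage3.data, fm.stage3.data)  # eval determinism


def test_backbone_default_config_channels():
    cfg = BackboneConfig()
    assert cfg.stage_channels == (64, 128, 256)
    assert cfg.cot_enabled_stages == (2, 3)
    with pytest.raises(ValueError, match="spatial|minimum"):
        manual_seed(11)
        CoTResNet3D(BackboneConfig(stem_channels=8, stage_channels=(8, 8, 8),
                                   blocks_per_stage=(1, 1, 1), cot_enabled_stages=(),
                                   se_enabled=False))(tensor(1, 1, 6, 6, 6))
    with pytest.raises(ValueError, match="channel"):
        manual_seed(12)
        CoTResNet3D(BackboneConfig(stem_channels=8, stage_channels=(8, 8, 8),
                                   blocks_per_stage=(1, 1, 1), cot_enabled_stages=(),
                                   se_enabled=False))(tensor(1, 3, 16, 16, 16))


def test_gated_backbone_reduces_to_plain_resnet():
    """With CoT gates at 0 and SE off, the backbone equals a plain 3D ResNet
    of the same widths under weight copy."""
    widths = BackboneConfig(stem_channels=8, stage_channels=(8, 16, 32),
                            blocks_per_stage=(1, 1, 1), se_enabled=False)
    manual_seed(13)
    cot_bb = CoTResNet3D(widths)
    manual_seed(14)
    plain_bb = CoTResNet3D(BackboneConfig(stem_channels=8, stage_channels=(8, 16, 32),
                                          blocks_per_stage=(1, 1, 1),
                                          cot_enabled_stages=(), se_enabled=False))
    shared = plain_bb.state_dict()
    cot_state = cot_bb.state_dict()
    plain_bb.load_state_dict({k: cot_state[k] for k in shared})
    for m in cot_bb.modules():
        if isinstance(m, CoT3d):
            m.gate.data[:] = 0.0
    cot_bb.eval()
    plain_bb.eval()
    x = tensor(1, 1, 20, 24, 20)
    np.testing.assert_allclose(cot_bb(x).stage3.data, plain_bb(x).stage3.data,
                               atol=1e-6)
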