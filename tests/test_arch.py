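"""Architecture contracts: output-size arithmetic, attention semantics,
bridge-path behaviour, bottleneck blocks and the forward shape contract."""

import numpy as np
import pytest

from fundusseg import nn
from fundusseg.arch import (GICBlock, MDCBlock, ModelConfig, RSAPNet,
                            RSAPPath, SpatialAttention, cross_entropy_loss,
                            dilated_out_size, load_checkpoint,
                            mdc_receptive_field, save_checkpoint)


# ------------------------------------------------------------- output sizes
@pytest.mark.parametrize("args,expected", [
    ((512, 2, 2, 3, 1), 512),   # "same" padding for a d=2 3x3 conv
    ((512, 0, 1, 2, 2), 256),   # the 2x2 stride-2 branch
    ((7, 0, 1, 3, 1), 5),
    ((16, 0, 1, 5, 5), 3),      # 5x5 max pool, stride = kernel
])
def test_dilated_out_size_examples(args, expected):
    assert dilated_out_size(*args) == expected


def test_dilated_out_size_rejects_bad_arguments():
    with pytest.raises(ValueError):
        dilated_out_size(2, 0, 1, 5, 1)   # non-positive output
    with pytest.raises(ValueError):
        dilated_out_size(16, -1, 1, 3, 1)
    with pytest.raises(ValueError):
        dilated_out_size(16, 0, 0, 3, 1)


def test_mdc_deepest_branch_receptive_field_is_17():
    assert mdc_receptive_field((1, 2, 5)) == 17


# ------------------------------------------------------- spatial attention
def test_attention_max_equals_avg_when_channels_identical(rng):
    x = np.repeat(rng.normal(size=(1, 1, 5, 5)), 4, axis=1)
    t = nn.Tensor(x)
    mx, av = nn.channel_max(t), nn.channel_mean(t)
    np.testing.assert_allclose(mx.data, av.data, atol=1e-12)


def test_attention_output_is_one_channel_map(rng):
    att = SpatialAttention(np.random.default_rng(0))
    out = att(nn.Tensor(rng.normal(size=(2, 7, 6, 6))))
    assert out.shape == (2, 1, 6, 6)


def test_attention_with_frozen_identity_kernel_returns_leaky_of_max(rng):
    att = SpatialAttention(np.random.default_rng(0), slope=0.01)
    kernel = np.zeros((1, 2, 3, 3))
    kernel[0, 0, 1, 1] = 1.0  # centre-only identity on the max plane
    att.conv.weight.data = kernel.astype(np.float32)
    att.conv.bias.data[:] = 0.0
    x = rng.normal(size=(1, 3, 4, 4)).astype(np.float32)
    out = att(nn.Tensor(x))
    expected = x.max(axis=1, keepdims=True)
    expected = np.where(expected > 0, expected, 0.01 * expected)
    np.testing.assert_allclose(out.data, expected, atol=1e-6)


# ------------------------------------------------------------- RSAP bridge
def _freeze_residual_identity(block):
    """Make a residual block the identity map (zero convs, unit BN)."""
    block.conv1.conv.weight.data[:] = 0.0
    block.conv2.weight.data[:] = 0.0
    assert block.proj is None


def test_rsap_identity_blocks_and_unit_attention_pass_through(rng):
    path = RSAPPath(4, depth=1, rng=np.random.default_rng(0))
    _freeze_residual_identity(path.blocks[0])
    # force the attention map to 1 everywhere: zero kernel, bias 1/slope-free
    path.attention.conv.weight.data[:] = 0.0
    path.attention.conv.bias.data[:] = 1.0
    path.blocks[0].bn2.training = False
    path.blocks[0].conv1.bn.training = False
    x = rng.normal(size=(1, 4, 6, 6)).astype(np.float32)
    out = path(nn.Tensor(x))
    # identity shortcut; the block's closing activation remains
    lr = lambda a: np.where(a > 0, a, 0.01 * a)
    np.testing.assert_allclose(out.data, lr(x), atol=1e-5)


def test_rsap_zero_input_with_zero_bias_gives_zero_map():
    path = RSAPPath(3, depth=2, rng=np.random.default_rng(1))
    out = path(nn.Tensor(np.zeros((1, 3, 8, 8), np.float32)))
    np.testing.assert_allclose(out.data, 0.0, atol=1e-7)


def test_rsap_depth_zero_is_rejected():
    with pytest.raises(ValueError):
        RSAPPath(3, depth=0, rng=np.random.default_rng(0))


# ------------------------------------------------------------- MDC and GIC
def test_mdc_all_zero_convolutions_reduce_to_identity_branch(rng):
    mdc = MDCBlock(4, np.random.default_rng(0))
    for branch in (mdc.branch_a, mdc.branch_b, mdc.branch_c):
        for layer in branch:
            layer.conv.weight.data[:] = 0.0
    for fuse in (mdc.fuse_a, mdc.fuse_b, mdc.fuse_c):
        fuse.weight.data[:] = 0.0
        fuse.bias.data[:] = 0.0
    x = rng.normal(size=(1, 4, 8, 8)).astype(np.float32)
    out = mdc(nn.Tensor(x))
    np.testing.assert_allclose(out.data, x, atol=1e-7)


@pytest.mark.parametrize("size", [16, 32])
def test_mdc_preserves_spatial_size(size, rng):
    mdc = MDCBlock(3, np.random.default_rng(0))
    out = mdc(nn.Tensor(rng.normal(size=(1, 3, size, size)).astype(np.float32)))
    assert out.shape == (1, 3, size, size)


def test_gic_adds_exactly_four_channels(rng):
    gic = GICBlock(6, np.random.default_rng(0))
    out = gic(nn.Tensor(rng.normal(size=(1, 6, 16, 16)).astype(np.float32)))
    assert out.shape == (1, 10, 16, 16)


def test_gic_pooled_size_follows_output_formula(rng):
    gic = GICBlock(2, np.random.default_rng(0))
    x = nn.Tensor(rng.normal(size=(1, 2, 16, 16)).astype(np.float32))
    pooled = nn.max_pool2d(x, 5)
    assert pooled.shape[-1] == dilated_out_size(16, 0, 1, 5, 5) == 3


def test_gic_constant_input_pooling_branches_stay_constant():
    x = nn.Tensor(np.full((1, 2, 12, 12), 3.5, np.float32))
    pooled = nn.max_pool2d(x, 6)
    up = nn.bilinear_resize(pooled, (12, 12))
    assert np.allclose(up.data, 3.5)


def test_gic_rejects_too_small_feature_maps(rng):
    gic = GICBlock(2, np.random.default_rng(0))
    with pytest.raises(ValueError):
        gic(nn.Tensor(rng.normal(size=(1, 2, 4, 4)).astype(np.float32)))


# ------------------------------------------------------------------ forward
def test_forward_contract_small_input(rng):
    cfg = ModelConfig(input_size=64, base_channels=4, gic_pool_sizes=(2, 2),
                      gic_conv_specs=((2, 2), (2, 2)), seed=3)
    net = RSAPNet(cfg)
    out = net(rng.normal(size=(2, 3, 64, 64)).astype(np.float32))
    assert out.shape == (2, 3, 64, 64)
    assert [s[2:] for s in net.encoder_scale_shapes_] == \
        [(32, 32), (16, 16), (8, 8), (4, 4), (2, 2)]
    channels = [s[1] for s in net.encoder_scale_shapes_]
    assert channels == [4, 8, 16, 32, 64]


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(input_size=100)
    with pytest.raises(ValueError):
        ModelConfig(n_classes=2)
    with pytest.raises(ValueError):
        ModelConfig(rsap_depths=(1, 2))
    with pytest.raises(ValueError):
        ModelConfig(encoder_stage_channels=(8, 16))


def test_construction_is_deterministic():
    cfg = ModelConfig(input_size=64, base_channels=4, gic_pool_sizes=(2, 2),
                      gic_conv_specs=((2, 2), (2, 2)), seed=9)
    a, b = RSAPNet(cfg), RSAPNet(cfg)
    pa, pb = a.parameters(), b.parameters()
    assert len(pa) == len(pb)
    for x, y in zip(pa, pb):
        np.testing.assert_array_equal(x.data, y.data)


def test_default_instantiation_structure():
    cfg = ModelConfig()
    net = RSAPNet(cfg)
    assert net.n_bridges == 3
    assert cfg.n_classes == 3
    assert set(cfg.mdc_dilations) == {1, 2, 5}
    assert cfg.rsap_depths == (3, 2, 1)
    assert [len(b.blocks) for b in net.bridges] == [3, 2, 1]


def test_bridgeless_config_is_plain_encoder_decoder(rng):
    cfg = ModelConfig(input_size=64, base_channels=4, gic_pool_sizes=(2, 2),
                      gic_conv_specs=((2, 2), (2, 2)),
                      rsap_depths=(0, 0, 0), seed=0)
    net = RSAPNet(cfg)
    assert net.n_bridges == 0
    out = net(rng.normal(size=(1, 3, 64, 64)).astype(np.float32))
    assert out.shape == (1, 3, 64, 64)


def test_checkpoint_roundtrip(tmp_path, rng):
    cfg = ModelConfig(input_size=64, base_channels=4, gic_pool_sizes=(2, 2),
                      gic_conv_specs=((2, 2), (2, 2)), seed=5)
    net = RSAPNet(cfg)
    x = rng.normal(size=(1, 3, 64, 64)).astype(np.float32)
    net.eval()
    ref = net(x).data
    path = tmp_path / "weights.npz"
    save_checkpoint(net, path)
    loaded = load_checkpoint(path)
    loaded.eval()
    np.testing.assert_allclose(loaded(x).data, ref, atol=1e-6)


# --------------------------------------------------------------------- loss
def test_cross_entropy_zero_logits_is_log3():
    for c in range(3):
        assert cross_entropy_loss(np.zeros(3), c) == \
            pytest.approx(np.log(3.0), abs=1e-9)


def test_cross_entropy_example_arithmetic():
    assert cross_entropy_loss(np.array([1.0, 2.0, 3.0]), 2) == \
        pytest.approx(-3 + np.log(np.e + np.e ** 2 + np.e ** 3), abs=1e-9)


def test_cross_entropy_saturates_for_confident_logit():
    assert cross_entropy_loss(np.array([50.0, 0.0, 0.0]), 0) < 1e-12


def test_cross_entropy_rejects_out_of_range_class():
    with pytest.raises(ValueError):
        cross_entropy_loss(np.zeros(3), 3)
    with pytest.raises(ValueError):
        cross_entropy_loss(nn.Tensor(np.zeros((1, 3, 2, 2))),
                           np.full((1, 2, 2), 5))


def test_cross_entropy_shift_invariance(rng):
    logits = rng.normal(size=(1, 3, 4, 4))
    target = rng.integers(0, 3, size=(1, 4, 4))
    a = cross_entropy_loss(nn.Tensor(logits), target)
    b = cross_entropy_loss(nn.Tensor(logits + 17.3), target)
    assert float(a.data) == pytest.approx(float(b.data), abs=1e-9)
    assert float(a.data) > 0
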