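"""Architecture contracts: channel plans, dual-encoder size arithmetic,
skip-fusion variants against the scalar reference, ablation structure,
end-to-end differentiability."""

import numpy as np
import pytest

from fsnet import nn
from fsnet.network import (ChannelPlan, EncoderBStage, FSNet, FsNetConfig,
                           SegmentationSubNet, SkipFusion, layer_inventory)
from fsnet.reference import skip_fuse_reference


def test_channel_plan_presets_and_sequence():
    plan32 = ChannelPlan.from_spec("(32)")
    assert plan32.sequence() == (1, 32, 64, 128, 256, 512, 256, 128, 64, 32, 1)
    plan16 = ChannelPlan.from_spec("(16)")
    assert plan16.sequence() == (1, 16, 32, 64, 128, 256, 128, 64, 32, 16, 1)
    with pytest.raises(ValueError):
        ChannelPlan((8, 24))  # widths must double


@pytest.mark.parametrize("pattern", ["2x2-0101", "2x2-1010"])
@pytest.mark.parametrize("size", [32, 50, 128])
def test_encoder_b_stage_preserves_spatial_size(pattern, size, rng):
    nn.manual_seed(1)
    stage = EncoderBStage(1, 8, pattern)
    x = nn.Tensor(rng.random((1, 1, size, size)).astype(np.float32))
    assert stage(x).shape == (1, 8, size, size)


def test_dual_encoder_pyramid_shapes(tiny_net_config, rng):
    nn.manual_seed(2)
    seg = SegmentationSubNet(tiny_net_config)
    fused = nn.Tensor(rng.random((1, 1, 32, 32)).astype(np.float32))
    fa, fb, bottleneck = seg.dual_encode(fused)
    sizes = [32, 16, 8, 4]
    chans = [8, 16, 32, 64]
    for a, b, s, c in zip(fa, fb, sizes, chans):
        assert a.shape == (1, c, s, s)
        assert b.shape == a.shape
    assert bottleneck.shape == (1, 128, 2, 2)


def test_indivisible_input_rejected(tiny_net_config, rng):
    seg = SegmentationSubNet(tiny_net_config)
    with pytest.raises(ValueError):
        seg.dual_encode(nn.Tensor(rng.random((1, 1, 24, 24)).astype(np.float32)))


@pytest.mark.parametrize("variant", ["a", "b", "c", "d"])
def test_skip_variants_emit_double_width(variant, rng):
    nn.manual_seed(3)
    skip = SkipFusion(8, 16, variant)
    x1 = nn.Tensor(rng.random((2, 8, 8, 8)).astype(np.float32))
    x2 = nn.Tensor(rng.random((2, 8, 8, 8)).astype(np.float32))
    deep = nn.Tensor(rng.random((2, 16, 4, 4)).astype(np.float32))
    assert skip(x1, x2, deep).shape == (2, 16, 8, 8)


def test_skip_variant_d_matches_scalar_reference(rng):
    nn.manual_seed(4)
    skip = SkipFusion(8, 16, "d", dtype=np.float64)
    x1 = rng.normal(size=(1, 8, 8, 8))
    x2 = rng.normal(size=(1, 8, 8, 8))
    deep = rng.normal(size=(1, 16, 4, 4))
    got = skip(nn.Tensor(x1), nn.Tensor(x2), nn.Tensor(deep)).data[0]
    u = skip.up(nn.Tensor(deep)).data[0]
    ref = skip_fuse_reference(skip, x1[0], x2[0], u)
    assert np.abs(got - ref).max() <= 1e-5


def test_skip_variant_d_zero_reductions_kill_output(rng):
    nn.manual_seed(5)
    skip = SkipFusion(8, 16, "d", dtype=np.float64)
    for conv in (skip.reduce1, skip.reduce2):
        conv.weight.data[...] = 0.0
        conv.bias.data[...] = 0.0
    out = skip(nn.Tensor(rng.normal(size=(1, 8, 8, 8))),
               nn.Tensor(rng.normal(size=(1, 8, 8, 8))),
               nn.Tensor(rng.normal(size=(1, 16, 4, 4))))
    np.testing.assert_array_equal(out.data, np.zeros_like(out.data))


def test_fusion_modes_and_ranges(tiny_net_config, rng):
    nn.manual_seed(6)
    net = FSNet(tiny_net_config)
    ct = nn.Tensor(rng.random((1, 1, 32, 32)).astype(np.float32))
    mri = nn.Tensor(rng.random((1, 1, 32, 32)).astype(np.float32))
    fused, recon = net.fusion_forward(ct, mri, mode="train")
    assert fused.shape == (1, 1, 32, 32) and recon.shape == (1, 2, 32, 32)
    assert fused.data.min() >= 0 and fused.data.max() <= 1
    fused_i, recon_i = net.fusion_forward(ct, mri, mode="inference")
    assert recon_i is None
    with pytest.raises(ValueError):
        net.fusion_forward(ct, mri, mode="bogus")
    with pytest.raises(ValueError):
        net.fusion_forward(ct, nn.Tensor(rng.random((1, 1, 16, 16)).astype(np.float32)))


def test_zeroed_reconstruction_decoder_outputs_half(tiny_net_config, rng):
    nn.manual_seed(7)
    net = FSNet(tiny_net_config)
    for p in net.fusion_decoder.parameters():
        p.data[...] = 0.0
    ct = nn.Tensor(rng.random((1, 1, 32, 32)).astype(np.float32))
    mri = nn.Tensor(rng.random((1, 1, 32, 32)).astype(np.float32))
    _, recon = net.fusion_forward(ct, mri, mode="train")
    np.testing.assert_allclose(recon.data, 0.5, atol=1e-7)


def test_forward_deterministic_in_eval_mode(tiny_net_config, rng):
    nn.manual_seed(8)
    net = FSNet(tiny_net_config)
    net.eval()
    ct = nn.Tensor(rng.random((2, 1, 32, 32)).astype(np.float32))
    mri = nn.Tensor(rng.random((2, 1, 32, 32)).astype(np.float32))
    p1, _, _ = net(ct, mri, mode="inference")
    p2, _, _ = net(ct, mri, mode="inference")
    np.testing.assert_array_equal(p1.data, p2.data)
    assert p1.data.min() >= 0 and p1.data.max() <= 1


def test_segmentation_gradients_reach_fusion_encoder(tiny_net_config, rng):
    """The cascade trains end to end: a loss on the probability map must
    propagate into E_theta."""
    nn.manual_seed(9)
    net = FSNet(tiny_net_config)
    ct = nn.Tensor(rng.random((1, 1, 32, 32)).astype(np.float32))
    mri = nn.Tensor(rng.random((1, 1, 32, 32)).astype(np.float32))
    prob, _, _ = net(ct, mri, mode="inference")
    (prob ** 2).mean().backward()
    fusion_grads = [p.grad for _, p in net.fusion_encoder.named_parameters()]
    assert any(g is not None and np.any(g != 0) for g in fusion_grads)


def test_non_fusion_ablation_averages_the_modalities(rng):
    cfg = FsNetConfig(channel_plan=(8, 16, 32, 64, 128), input_size=32,
                      use_fusion_subnet=False)
    nn.manual_seed(10)
    net = FSNet(cfg)
    ct = nn.Tensor(rng.random((1, 1, 32, 32)).astype(np.float32))
    mri = nn.Tensor(rng.random((1, 1, 32, 32)).astype(np.float32))
    fused, recon = net.fusion_forward(ct, mri)
    assert recon is None
    np.testing.assert_allclose(fused.data, (ct.data + mri.data) / 2, atol=1e-7)


def _expected_plain_unet_inventory(widths):
    """Parameter shapes of a textbook U-Net with BN, built from the plan
    arithmetic alone (independent of the model classes)."""
    shapes = []

    def double_conv(cin, cout):
        shapes.extend([(cout, cin, 3, 3), (cout,), (cout,), (cout,),
                       (cout, cout, 3, 3), (cout,), (cout,), (cout,)])

    stages, bottleneck = widths[:-1], widths[-1]
    prev = 1
    for w in stages:
        double_conv(prev, w)
        prev = w
    double_conv(stages[-1], bottleneck)
    deep = bottleneck
    for w in reversed(stages):
        shapes.extend([(deep, w, 2, 2), (w,)])  # transposed conv
        double_conv(2 * w, w)
        deep = w
    shapes.extend([(1, stages[0], 1, 1), (1,)])  # head
    return sorted(shapes)


def test_full_ablation_reduces_to_plain_unet():
    cfg = FsNetConfig(channel_plan="(32)", use_csab=False,
                      use_dual_encoder=False, use_fusion_subnet=False)
    nn.manual_seed(11)
    net = FSNet(cfg)
    got = sorted(shape for _, shape in layer_inventory(net))
    assert got == _expected_plain_unet_inventory((32, 64, 128, 256, 512))


@pytest.mark.parametrize("flag", ["use_csab", "use_dual_encoder", "use_fusion_subnet"])
def test_each_toggle_changes_only_its_subgraph(flag, tiny_net_config):
    base = dict(channel_plan=(8, 16, 32, 64, 128), input_size=32,
                fusion_widths=(8, 16, 32))
    nn.manual_seed(12)
    on = {name for name, _ in layer_inventory(FSNet(FsNetConfig(**base)))}
    nn.manual_seed(12)
    off = {name for name, _ in
           layer_inventory(FSNet(FsNetConfig(**{**base, flag: False})))}
    removed = on - off
    added = off - on
    assert removed, f"{flag} removed nothing"
    marker = {"use_csab": "csab", "use_dual_encoder": "encoder_b",
              "use_fusion_subnet": "fusion"}[flag]
    assert all(marker in name or
               ("use_dual_encoder" == flag and
                ("bottleneck_merge" in name or "reduce" in name or "csab2" in name))
               for name in removed), sorted(removed)
    if flag == "use_fusion_subnet":
        assert not added
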