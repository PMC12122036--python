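"""End-to-end assembly contracts: shapes, determinism, counters, gradients."""

import numpy as np
import pytest

from defifnet import autodiff as ad
from defifnet.autodiff import Tensor
from defifnet.network import (DEFIFNet, ModelConfig, count_macs,
                              count_parameters, summary, summary_text)
from defifnet.nn import Conv2d
from defifnet.objective import combined_loss


SMALL = ModelConfig(channels=(4, 4, 8, 8), bottleneck_width=8,
                    input_size=(64, 64), seed=7)


@pytest.fixture(scope="module")
def small_net():
    return DEFIFNet(SMALL)


def test_output_shape_and_range_across_input_sizes(small_net):
    for size in (32, 64, 128):
        x = np.random.default_rng(size).normal(
            size=(1, 3, size, size)).astype(np.float32) * 0.1
        y = small_net(x)
        assert y.shape == (1, 1, size, size)
        assert (y.data >= 0).all() and (y.data <= 1).all()


def test_eval_forward_deterministic(small_net):
    x = np.random.default_rng(0).normal(size=(2, 3, 32, 32)).astype(np.float32)
    small_net.eval()
    y1 = small_net(x).data
    y2 = small_net(x).data
    np.testing.assert_array_equal(y1, y2)


def test_identical_batches_identical_outputs(small_net):
    x = np.random.default_rng(3).normal(size=(1, 3, 32, 32)).astype(np.float32)
    small_net.eval()
    y = small_net(np.concatenate([x, x], axis=0)).data
    np.testing.assert_allclose(y[0], y[1], atol=1e-6)


def test_multiclass_probabilities_sum_to_one():
    cfg = ModelConfig(channels=(4, 4, 4, 4), bottleneck_width=4,
                      input_size=(32, 32), num_classes=3, seed=1)
    net = DEFIFNet(cfg)
    x = np.random.default_rng(1).normal(size=(1, 3, 32, 32)).astype(np.float32)
    y = net(x).data
    assert y.shape == (1, 3, 32, 32)
    np.testing.assert_allclose(y.sum(axis=1), 1.0, atol=1e-6)


def test_indivisible_input_size_rejected(small_net):
    with pytest.raises(ValueError, match="divisible"):
        small_net(np.zeros((1, 3, 40, 40), dtype=np.float32))


def test_gradients_defined_and_finite_for_all_parameters(small_net):
    rng = np.random.default_rng(5)
    x = rng.normal(size=(2, 3, 32, 32)).astype(np.float32) * 0.2
    g = (rng.random(size=(2, 1, 32, 32)) > 0.5).astype(np.float32)
    small_net.train()
    small_net.zero_grad()
    loss = combined_loss(small_net(x), g)
    loss.backward()
    for name, p in small_net.named_parameters():
        assert p.grad is not None, f"missing gradient for {name}"
        assert np.isfinite(p.grad).all(), f"non-finite gradient for {name}"


def test_encoder_level_is_fifconv_of_branch_sum(small_net):
    """The fused map equals FIFConv applied to the sum of both branches."""
    rng = np.random.default_rng(11)
    x = Tensor(rng.normal(size=(1, 3, 32, 32)).astype(np.float32))
    small_net.eval()
    left_out, fused = small_net.encoder_level(x, x, 0)
    assert left_out.shape == (1, 4, 32, 32) and fused.shape == (1, 4, 32, 32)
    enc = small_net.encoders[0]
    branch_sum = enc.block2(enc.block1(x)) + enc.gdf_conv(x)
    np.testing.assert_allclose(fused.data, enc.fif(branch_sum).data, atol=1e-6)


def test_encoder_level_with_zeroed_gdf_reduces_to_left_branch(small_net):
    rng = np.random.default_rng(13)
    x = Tensor(rng.normal(size=(1, 3, 32, 32)).astype(np.float32))
    small_net.eval()
    enc = small_net.encoders[0]
    saved_w = enc.gdf_conv.weight.data.copy()
    saved_b = enc.gdf_conv.bias.data.copy()
    try:
        enc.gdf_conv.weight.data[...] = 0.0
        enc.gdf_conv.bias.data[...] = 0.0
        left_out, fused = small_net.encoder_level(x, x, 0)
        np.testing.assert_allclose(fused.data, enc.fif(left_out).data,
                                   atol=1e-6)
    finally:
        enc.gdf_conv.weight.data = saved_w
        enc.gdf_conv.bias.data = saved_b


def test_decoder_level_residual_identity(small_net):
    """Output minus F1 equals FIFConv(F1) exactly, per the residual design."""
    rng = np.random.default_rng(17)
    small_net.eval()
    deep = Tensor(rng.normal(size=(1, 8, 8, 8)).astype(np.float32))
    skip = Tensor(rng.normal(size=(1, 8, 16, 16)).astype(np.float32))
    out = small_net.decoder_level(deep, skip, 0)
    assert out.shape == skip.shape
    dec = small_net.decoders[0]
    u = dec.up_conv(ad.upsample_bilinear2x(deep))
    f1 = dec.conv2(dec.conv1(ad.concat([u, skip])))
    np.testing.assert_allclose(out.data - f1.data, dec.fif(f1).data,
                               atol=1e-5)


def test_decoder_resolution_mismatch_rejected(small_net):
    deep = Tensor(np.zeros((1, 8, 8, 8), dtype=np.float32))
    skip = Tensor(np.zeros((1, 8, 32, 32), dtype=np.float32))
    with pytest.raises(ValueError, match="mismatch"):
        small_net.decoder_level(deep, skip, 0)


# ---------------------------------------------------------------------------
# Counters
# ---------------------------------------------------------------------------


class TestCounters:
    def test_single_1x1_conv_parameters(self):
        conv = Conv2d(4, 4, 1, np.random.default_rng(0))
        assert conv.num_parameters() == 4 * 4 + 4  # == 20

    def test_single_3x3_conv_parameters(self):
        conv = Conv2d(3, 8, 3, np.random.default_rng(0))
        assert conv.num_parameters() == 3 * 3 * 3 * 8 + 8  # == 224

    def test_single_1x1_conv_macs(self):
        conv = Conv2d(4, 4, 1, np.random.default_rng(0), bias=False)
        with ad.counting_macs() as c:
            conv(Tensor(np.zeros((1, 4, 8, 8), dtype=np.float32)))
        assert c[0] == 4 * 4 * 64  # == 1024

    def test_parameter_count_additive_over_composition(self, small_net):
        total = sum(child.num_parameters()
                    for _, child in small_net.children())
        assert count_parameters(small_net) == total

    def test_mac_count_additive_over_resolution_quadrupling(self, small_net):
        """All stages are resolution-linear except the channel-wise gates."""
        m32 = count_macs(small_net, (32, 32))
        m64 = count_macs(small_net, (64, 64))
        assert 0.999 < m64 / (4 * m32) < 1.001

    def test_halving_channels_roughly_quarters_macs(self):
        big = DEFIFNet(ModelConfig(channels=(8, 8, 16, 16), bottleneck_width=16,
                                   input_size=(32, 32)))
        half = DEFIFNet(ModelConfig(channels=(4, 4, 8, 8), bottleneck_width=8,
                                    input_size=(32, 32)))
        ratio = count_macs(big) / count_macs(half)
        assert 2.5 < ratio < 4.0  # input convs scale linearly, the rest ~x4

    def test_analytic_parameter_count_matches_measured(self):
        from defifnet.calibration import analytic_param_count

        for cs, cb in (((4, 4, 8, 44), 44), ((4, 8, 16, 32), 64)):
            cfg = ModelConfig(channels=cs, bottleneck_width=cb)
            assert analytic_param_count(cs, cb) == count_parameters(DEFIFNet(cfg))


def test_summary_report_consistent(small_net):
    rep = summary(small_net, (32, 32))
    txt = summary_text(small_net, (32, 32))
    assert str(rep["parameters"]) in txt
    assert rep["parameters"] == count_parameters(small_net)
    assert rep["parameters_M"] == round(rep["parameters"] / 1e6, 2)
    assert sum(e["parameters"] for e in rep["per_layer"]) == rep["parameters"]


def test_checkpoint_roundtrip(tmp_path, small_net):
    x = np.random.default_rng(23).normal(size=(1, 3, 32, 32)).astype(np.float32)
    small_net.eval()
    before = small_net(x).data
    path = tmp_path / "ckpt.npz"
    small_net.save(path)
    loaded = DEFIFNet.load(path)
    loaded.eval()
    np.testing.assert_array_equal(loaded(x).data, before)
    assert loaded.config == small_net.config
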