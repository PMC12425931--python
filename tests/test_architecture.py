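"""Block- and network-level contracts: channel arithmetic, ablation
consistency, degenerate cases, parameter accounting, checkpoints."""

import numpy as np
import pytest
from scipy import ndimage

from mdwcnet import nn
from mdwcnet.architecture import (ABLATION_PRESETS, BIEBBlock,
                                  BIEBChannelAttention, BIEBResidualBranch,
                                  DepthwiseSeparableConv, DFCBBlock,
                                  MSCAWBlock, NetworkConfig, ablation_config,
                                  build_network, count_parameters,
                                  load_checkpoint, save_checkpoint)
from mdwcnet.errors import ConfigurationError, InvalidInputError

R = lambda s=0: np.random.default_rng(s)
CFG = NetworkConfig()


# ---------------------------------------------------------------------- DS conv


class TestDepthwiseSeparable:
    def test_shape_and_linearity(self, rng):
        conv = DepthwiseSeparableConv(R(), 4, 8, 3)
        assert conv.forward(np.zeros((1, 4, 8, 8), dtype=np.float32)).max() == 0.0
        assert conv.forward(rng.random((1, 4, 8, 8), dtype=np.float32)).shape == (1, 8, 8, 8)

    def test_identity_kernel_preserves_input(self, rng):
        conv = DepthwiseSeparableConv(R(), 1, 1, 3)
        conv.depthwise.w.data[...] = 0
        conv.depthwise.w.data[0, 1, 1] = 1.0  # centred delta
        conv.pointwise.w.data[...] = 1.0
        x = rng.random((1, 1, 5, 5), dtype=np.float32)
        assert np.allclose(conv.forward(x), x, atol=1e-6)

    def test_matches_direct_convolution_oracle(self, rng):
        conv = DepthwiseSeparableConv(R(3), 3, 2, 5)
        x = rng.standard_normal((1, 3, 7, 9)).astype(np.float32)
        y = conv.forward(x)
        # oracle: per-channel correlation, then explicit channel mixing
        dw = np.stack(
            [ndimage.correlate(x[0, c].astype(np.float64),
                               conv.depthwise.w.data[c].astype(np.float64),
                               mode="constant") for c in range(3)]
        )
        expect = np.einsum("oc,chw->ohw", conv.pointwise.w.data.astype(np.float64), dw)
        assert np.abs(y[0] - expect).max() < 1e-4

    def test_even_kernel_rejected(self):
        with pytest.raises(ConfigurationError):
            DepthwiseSeparableConv(R(), 4, 8, 2)


# ------------------------------------------------------------- adaptive weights


class TestAdaptiveWeighting:
    def test_identity_and_annihilation(self, rng):
        x = rng.random((2, 4, 5, 5), dtype=np.float32)
        layer = nn.AdaptiveChannelWeight(4)
        assert np.array_equal(layer.forward(x), x)  # weights start at 1
        layer.w.data[...] = 0
        assert layer.forward(x).max() == 0.0

    def test_weight_gradient_is_input_sum_under_sum_loss(self, rng):
        # with L = sum(y) and one channel, dL/dw is exactly sum(x)
        x = rng.random((1, 1, 6, 6), dtype=np.float32)
        layer = nn.AdaptiveChannelWeight(1)
        layer.forward(x)
        layer.backward(np.ones_like(x))
        assert np.isclose(layer.w.grad[0], x.sum(), rtol=1e-5)
        # and it matches a central finite difference at step 1e-4
        eps = 1e-4
        layer.w.data[...] = 1 + eps
        lp = layer.forward(x).sum()
        layer.w.data[...] = 1 - eps
        lm = layer.forward(x).sum()
        assert np.isclose(layer.w.grad[0], (lp - lm) / (2 * eps), rtol=1e-2)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            nn.AdaptiveChannelWeight(3).forward(rng.random((1, 4, 2, 2), dtype=np.float32))


# ---------------------------------------------------------------------- MSCAW


class TestMSCAW:
    def test_shape_contract_and_zero_propagation(self, rng):
        block = MSCAWBlock(R(), 16, 64, CFG)
        assert block.forward(rng.random((1, 16, 32, 32), dtype=np.float32)).shape == (1, 64, 32, 32)
        assert np.abs(block.forward(np.zeros((1, 16, 32, 32), dtype=np.float32))).max() == 0.0

    def test_unit_weights_equal_weighting_disabled_variant(self, rng):
        # identical seeds give identical conv/BN weights; with the adaptive
        # weights at their initial value 1 the two variants must agree
        # bit-for-bit
        cfg_off = NetworkConfig(use_mscaw_weighting=False)
        a = MSCAWBlock(R(5), 8, 16, CFG)
        b = MSCAWBlock(R(5), 8, 16, cfg_off)
        x = rng.random((2, 8, 16, 16), dtype=np.float32)
        assert np.array_equal(a.forward(x), b.forward(x))

    def test_indivisible_out_channels_rejected(self):
        with pytest.raises(ConfigurationError):
            MSCAWBlock(R(), 8, 30, CFG)


# ------------------------------------------------------------- channel softmax


class TestChannelSoftmax:
    def test_uniform_single_and_exact_cases(self):
        sm = nn.ChannelSoftmax()
        const = sm.forward(np.full((1, 4, 3, 3), 7.0, dtype=np.float32))
        assert np.allclose(const, 0.25, atol=1e-7)
        one = sm.forward(np.random.default_rng(0).random((2, 1, 4, 4)).astype(np.float32))
        assert np.allclose(one, 1.0, atol=1e-7)
        x = np.zeros((1, 2, 1, 1), dtype=np.float32)
        x[0, 1] = np.log(3.0)
        assert np.allclose(sm.forward(x)[0, :, 0, 0], [0.25, 0.75], atol=1e-6)

    def test_sums_to_one_even_for_extreme_logits(self, rng):
        sm = nn.ChannelSoftmax()
        x = (rng.standard_normal((2, 6, 5, 5)) * 20).astype(np.float32)
        y = sm.forward(x)
        assert np.all(y > 0) and np.allclose(y.sum(axis=1), 1.0, atol=1e-6)


# ----------------------------------------------------------------------- DFCB


class TestDFCB:
    def test_channel_contract(self, rng):
        block = DFCBBlock(R(), 64, CFG)
        out = block.forward(rng.random((1, 64, 32, 32), dtype=np.float32),
                            rng.random((1, 128, 32, 32), dtype=np.float32))
        assert out.shape == (1, 64, 32, 32)

    def test_zero_encoder_zeroes_first_half(self, rng):
        block = DFCBBlock(R(), 8, CFG)
        out = block.forward(np.zeros((1, 8, 4, 4), dtype=np.float32),
                            rng.random((1, 16, 4, 4), dtype=np.float32))
        assert np.abs(out[:, :4]).max() == 0.0

    def test_single_channel_softmax_degenerates_to_pass_through(self, rng):
        # with C//2 == 1 the softmax map is identically 1, so both gated
        # halves equal the raw path outputs
        block = DFCBBlock(R(), 2, CFG)
        enc = rng.random((1, 2, 6, 6), dtype=np.float32)
        dec = rng.random((1, 4, 6, 6), dtype=np.float32)
        out = block.forward(enc, dec)
        assert np.allclose(out[:, 0], block.enc_path.forward(enc, True)[:, 0], atol=1e-6)
        assert np.allclose(out[:, 1], block.dec_conv.forward(dec, True)[:, 0], atol=1e-6)

    @pytest.mark.parametrize("enc_shape,dec_shape", [
        ((1, 8, 4, 4), (1, 12, 4, 4)),   # wrong decoder channel count
        ((1, 8, 4, 4), (1, 16, 8, 8)),   # spatial mismatch
    ])
    def test_contract_violations_rejected(self, rng, enc_shape, dec_shape):
        block = DFCBBlock(R(), 8, CFG)
        with pytest.raises(ConfigurationError):
            block.forward(rng.random(enc_shape, dtype=np.float32),
                          rng.random(dec_shape, dtype=np.float32))


# ----------------------------------------------------------------------- BIEB


def _zero_params(block):
    for p in block.params():
        p.data[...] = 0


class TestBIEB:
    def test_zero_mlp_gives_half_gate(self, rng):
        att = BIEBChannelAttention(R(), 8, 2)
        _zero_params(att)
        x = rng.random((2, 8, 4, 4), dtype=np.float32)
        assert np.allclose(att.forward(x), x / 2, atol=1e-6)  # sigmoid(0) = 0.5

    def test_gate_strictly_inside_unit_interval(self, rng):
        att = BIEBChannelAttention(R(2), 8, 4)
        x = (rng.standard_normal((2, 8, 5, 5)) * 5).astype(np.float32)
        att.forward(x)
        z = att._z
        assert np.all(z > 0) and np.all(z < 1)

    def test_constant_channel_collapses_avg_and_max_paths(self):
        att = BIEBChannelAttention(R(3), 4, 2)
        x = np.ones((1, 4, 4, 4), dtype=np.float32) * np.arange(1, 5, dtype=np.float32)[None, :, None, None]
        att.forward(x)
        assert np.allclose(att._a[2], att._m[2], atol=1e-6)

    def test_reduction_must_be_smaller_than_channels(self):
        with pytest.raises(ConfigurationError):
            BIEBChannelAttention(R(), 8, 8)

    def test_residual_bookkeeping(self, rng):
        branch = BIEBResidualBranch(R(4), 16, CFG)
        x = rng.standard_normal((1, 16, 8, 8)).astype(np.float32)
        out = branch.forward(x)
        assert out.shape == x.shape
        delta_applied = branch.delta.w.data[None, :, None, None] * branch.weighted
        assert np.allclose(out - delta_applied, branch.residual, atol=1e-6)

    def test_zeroed_residual_branch_passes_input_through(self, rng):
        branch = BIEBResidualBranch(R(), 4, CFG)
        _zero_params(branch)
        x = rng.random((1, 4, 4, 4), dtype=np.float32)
        assert np.allclose(branch.forward(x), x, atol=1e-7)  # only the skip survives

    def test_single_branch_configs_equal_their_branch(self, rng):
        x = rng.random((1, 8, 4, 4), dtype=np.float32)
        upper = BIEBBlock(R(6), 8, NetworkConfig(use_bieb_lower=False, mlp_reduction=2))
        assert np.array_equal(upper.forward(x), upper.upper.forward(x))
        lower = BIEBBlock(R(6), 8, NetworkConfig(use_bieb_upper=False, mlp_reduction=2))
        assert np.array_equal(lower.forward(x), lower.lower.forward(x))

    def test_both_branches_disabled_rejected(self):
        with pytest.raises(ConfigurationError):
            NetworkConfig(use_bieb_upper=False, use_bieb_lower=False)


# --------------------------------------------------------------- full network


class TestNetwork:
    def test_logit_shapes_track_input_size(self, rng):
        net = build_network(seed=0)
        for size in (256, 128):
            x = rng.random((1, 1, size, size), dtype=np.float32)
            assert net.forward(x, train=False).shape == (1, 2, size, size)

    def test_input_contract_enforced(self, rng):
        net = build_network(seed=0)
        with pytest.raises(InvalidInputError):
            net.forward(rng.random((1, 3, 64, 64), dtype=np.float32))
        with pytest.raises(InvalidInputError):
            net.forward(rng.random((1, 1, 60, 60), dtype=np.float32))

    def test_every_ablation_preset_builds_and_runs(self, rng):
        x = rng.random((1, 1, 32, 32), dtype=np.float32)
        cfg_small = dict(encoder_widths=(8, 16, 32, 64), mlp_reduction=4)
        for name in ABLATION_PRESETS:
            net = build_network(ablation_config(name, **cfg_small), seed=0)
            assert net.forward(x, train=False).shape == (1, 2, 32, 32), name

    def test_invalid_widths_rejected(self):
        with pytest.raises(ConfigurationError):
            NetworkConfig(encoder_widths=(64, 64, 128, 256))
        with pytest.raises(ConfigurationError):
            NetworkConfig(encoder_widths=(6, 12, 24, 48))  # not divisible by 4
        with pytest.raises(ConfigurationError):
            NetworkConfig(encoder_widths=(64, 128, 192, 384))  # no doubling ladder


class TestParameterCount:
    def test_hand_counts(self):
        assert count_parameters_of(nn.PointwiseConv(R(), 4, 8)) == 32
        assert count_parameters_of(DepthwiseSeparableConv(R(), 4, 8, 3)) == 4 * 9 + 4 * 8

    def test_deterministic_across_constructions(self):
        assert count_parameters(build_network(seed=0)) == count_parameters(build_network(seed=99))

    def test_default_is_lighter_than_unet_baseline(self):
        default = count_parameters(build_network(seed=0))
        baseline = count_parameters(build_network(ablation_config("baseline_unet"), seed=0))
        assert default < baseline

    def test_disabling_adaptive_weighting_removes_exactly_those_scalars(self):
        full = count_parameters(build_network(seed=0))
        off = count_parameters(build_network(NetworkConfig(use_mscaw_weighting=False), seed=0))
        w = NetworkConfig().encoder_widths
        # one weight per channel of every level block output (enc, widen, dec)
        expected = sum(w) + 2 * w[-1] + sum(w)
        assert full - off == expected


def count_parameters_of(layer) -> int:
    return sum(p.data.size for p in layer.params())


class TestCheckpoints:
    def test_roundtrip_reproduces_outputs(self, rng, tmp_path):
        cfg = NetworkConfig(encoder_widths=(8, 16, 32, 64), mlp_reduction=4)
        net = build_network(cfg, seed=3)
        x = rng.random((1, 1, 32, 32), dtype=np.float32)
        net.forward(x, train=True)  # populate running stats
        y = net.forward(x, train=False)
        save_checkpoint(net, tmp_path / "ckpt.npz")
        restored = load_checkpoint(tmp_path / "ckpt.npz")
        assert restored.cfg == cfg
        assert np.array_equal(restored.forward(x, train=False), y)

    def test_missing_sidecar_config_rejected(self, tmp_path):
        np.savez(tmp_path / "orphan.npz", a=np.zeros(1))
        with pytest.raises(InvalidInputError):
            load_checkpoint(tmp_path / "orphan.npz")
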